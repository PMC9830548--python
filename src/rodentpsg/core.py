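"""Core containers shared across the pipeline.

Conventions used throughout the package:

* time is measured in seconds from record start; intervals are half-open
  ``[onset, offset)``;
* all sample indices are 0-based;
* signal amplitudes are in millivolts unless a channel's ``units`` entry
  says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "FormatError",
    "InputError",
    "ParameterError",
    "ChannelRole",
    "SignalRecord",
    "Hypnogram",
    "EventInterval",
    "SpectralEstimate",
    "normalize_intervals",
    "intervals_to_mask",
    "mask_to_intervals",
    "STATES",
    "EEG_LEFT",
    "EEG_RIGHT",
    "EMG",
]


class ConfigurationError(ValueError):
    """A role map, design table or config section is inconsistent."""


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class InputError(ValueError):
    """Input data violate an operation's preconditions."""


class ParameterError(ValueError):
    """A numeric parameter is out of its admissible range."""


#: canonical vigilance states (plus the pseudo-state used for masked epochs)
STATES = ("wake", "NREM", "REM")
ARTIFACT = "artifact"

EEG_LEFT = "eeg_left"
EEG_RIGHT = "eeg_right"
EMG = "emg"
_ROLES = (EEG_LEFT, EEG_RIGHT, EMG)


@dataclass(frozen=True)
class ChannelRole:
    """Binding of a channel name to its physiological role."""

    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ConfigurationError(
                f"unknown role {self.role!r}; expected one of {_ROLES}"
            )


def normalize_intervals(
    intervals: Iterable[tuple[float, float]], merge_gap_s: float = 0.0
) -> list[tuple[float, float]]:
    """Sort half-open intervals and merge overlaps and gaps < ``merge_gap_s``."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"empty or inverted interval [{a}, {b})")
        if out and a - out[-1][1] < merge_gap_s or (out and a <= out[-1][1]):
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def intervals_to_mask(
    intervals: Sequence[tuple[float, float]], rate: float, n_samples: int
) -> np.ndarray:
    """Boolean per-sample mask (True inside any interval)."""
    mask = np.zeros(n_samples, dtype=bool)
    for a, b in intervals:
        i = max(0, int(np.ceil(a * rate - 1e-9)))
        j = min(n_samples, int(np.ceil(b * rate - 1e-9)))
        mask[i:j] = True
    return mask


def mask_to_intervals(mask: np.ndarray, rate: float) -> list[tuple[float, float]]:
    """Half-open time intervals of the True runs of a boolean mask."""
    if mask.size == 0 or not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return [(s / rate, e / rate) for s, e in zip(starts, stops)]


@dataclass
class SignalRecord:
    """Multichannel continuous record on a single uniform time grid.

    ``channels`` maps channel name to its sample vector; ``roles`` maps
    channel name to one of ``eeg_left``/``eeg_right``/``emg``.
    ``artifact_mask`` holds half-open ``[s, s)`` intervals flagged invalid.
    """

    channels: dict[str, np.ndarray]
    rate: float
    roles: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    start_time: float = 0.0
    artifact_mask: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise InputError(f"channels differ in length: {sorted(lengths)}")
        for name in self.channels:
            self.units.setdefault(name, "mV")
        counts: dict[str, int] = {}
        for name, role in self.roles.items():
            if name not in self.channels:
                raise ConfigurationError(f"role assigned to unknown channel {name!r}")
            counts[role] = counts.get(role, 0) + 1
        for role, n in counts.items():
            if n > 1:
                raise ConfigurationError(f"role {role!r} assigned {n} times")
        self.artifact_mask = normalize_intervals(self.artifact_mask) if self.artifact_mask else []
        for a, b in self.artifact_mask:
            if a < 0 or b > self.duration_s + 1 / self.rate:
                raise InputError(f"artifact interval [{a}, {b}) outside record")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel_for(self, role: str) -> str:
        for name, r in self.roles.items():
            if r == role:
                return name
        raise ConfigurationError(f"no channel with role {role!r}")

    @property
    def eeg_names(self) -> tuple[str, str]:
        return self.channel_for(EEG_LEFT), self.channel_for(EEG_RIGHT)

    @property
    def emg_name(self) -> str:
        return self.channel_for(EMG)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def artifact_sample_mask(self) -> np.ndarray:
        return intervals_to_mask(self.artifact_mask, self.rate, self.n_samples)

    def copy(self) -> "SignalRecord":
        return SignalRecord(
            channels={k: v.copy() for k, v in self.channels.items()},
            rate=self.rate,
            roles=dict(self.roles),
            units=dict(self.units),
            start_time=self.start_time,
            artifact_mask=list(self.artifact_mask),
        )


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels on a fixed 10-s grid anchored at t=0.

    ``sub_labels`` keeps the per-second provisional states that the >5 s
    dominance rule aggregated, so events can be state-assigned at 1-s
    resolution.
    """

    labels: list[str]
    sub_labels: np.ndarray  # one string per second, len >= 10 * n_epochs
    epoch_len_s: float = 10.0

    def __post_init__(self) -> None:
        allowed = set(STATES) | {ARTIFACT}
        bad = set(self.labels) - allowed
        if bad:
            raise InputError(f"unknown state labels: {sorted(bad)}")
        self.sub_labels = np.asarray(self.sub_labels, dtype="U8")
        if len(self.sub_labels) < self.epoch_len_s * len(self.labels):
            raise InputError("sub_labels shorter than the epoch grid")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def span_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def state_at(self, t_s: float) -> str:
        """Scored state at time ``t_s``.

        Returns the containing epoch's label (the scored state); seconds
        past the epoch grid fall back to the provisional sub-label. Epoch
        labels are used rather than sub-labels because a large event
        distorts the 1-s features under itself while the surrounding
        epoch's score remains valid.
        """
        if t_s < 0 or int(t_s) >= len(self.sub_labels):
            raise InputError(f"time {t_s} s outside hypnogram span")
        e = int(t_s // self.epoch_len_s)
        if e < self.n_epochs:
            return self.labels[e]
        return str(self.sub_labels[int(t_s)])

    def epoch_starts(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_len_s

    def epoch_seconds(self, state: str) -> float:
        return sum(1.0 for lab in self.labels if lab == state) * self.epoch_len_s


_EVENT_RULES = {
    # kind: (band_lo, band_hi, min_dur strict >, max_dur or None)
    "SWD": (6.0, 12.0, 1.0, None),
    "SSWD": (3.0, 6.0, 1.0, None),
    "spindle": (10.0, 15.0, 0.5, 5.0),
}

LATERALITIES = ("bilateral", "left", "right")


@dataclass
class EventInterval:
    """One detected discharge or spindle, half-open in seconds."""

    onset_s: float
    offset_s: float
    kind: str
    band_lo_hz: float
    band_hi_hz: float
    peak_freq_hz: float
    laterality: str
    state: str
    channel_roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_RULES:
            raise InputError(f"unknown event kind {self.kind!r}")
        if self.offset_s <= self.onset_s:
            raise InputError("offset must exceed onset")
        lo, hi, min_dur, max_dur = _EVENT_RULES[self.kind]
        if (self.band_lo_hz, self.band_hi_hz) != (lo, hi):
            raise InputError(
                f"{self.kind} band must be [{lo}, {hi}] Hz, got "
                f"[{self.band_lo_hz}, {self.band_hi_hz}]"
            )
        d = self.duration_s
        if self.kind == "spindle":
            if not (min_dur <= d <= max_dur):
                raise InputError(f"spindle duration {d:.3f} s outside [{min_dur}, {max_dur}] s")
        elif d <= min_dur:
            raise InputError(f"{self.kind} duration {d:.3f} s must exceed {min_dur} s")
        if not (lo <= self.peak_freq_hz <= hi):
            raise InputError(
                f"peak frequency {self.peak_freq_hz:.2f} Hz outside band [{lo}, {hi}]"
            )
        if self.laterality not in LATERALITIES:
            raise InputError(f"unknown laterality {self.laterality!r}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, other: "EventInterval") -> bool:
        return self.onset_s < other.offset_s and other.onset_s < self.offset_s


@dataclass
class SpectralEstimate:
    """One-sided multitaper power spectral density."""

    freqs: np.ndarray  # Hz, strictly increasing
    psd: np.ndarray  # mV^2/Hz
    window_s: float
    nw: float
    n_tapers: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.ndim != 1 or self.psd.shape != self.freqs.shape:
            raise InputError("freqs and psd must be 1-D and equal length")
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0:
            raise InputError("freqs must be non-negative and strictly increasing")
        if np.any(self.psd < 0):
            raise InputError("psd must be non-negative")

    def band_power(self, lo_hz: float, hi_hz: float) -> float:
        """Mean psd over bins with lo <= f <= hi (a band-average density)."""
        sel = (self.freqs >= lo_hz) & (self.freqs <= hi_hz)
        if not sel.any():
            raise InputError(f"no frequency bins in [{lo_hz}, {hi_hz}] Hz")
        return float(self.psd[sel].mean())

    def total_power(self) -> float:
        """Integral of the density over the full one-sided axis."""
        return float(np.trapezoid(self.psd, self.freqs))
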