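"""Ground-truthed synthetic mouse polysomnography.

The generator realizes the same criteria the analysis stages assume:

* a semi-Markov wake/NREM/REM alternation (wake->NREM; NREM->wake or
  ->REM; REM->wake or ->NREM) with log-normal dwell times;
* EEG per channel = 1/f background + a state-gated delta (0.5-4 Hz)
  component in NREM and theta (6-10 Hz) component in REM, with 0.5-s
  crossfades; the two EEG channels share the common signal plus
  independent noise;
* EMG = white noise with state-gated RMS (high in wake, atonia in REM);
* injected SWD/SSWD trains (stylized biphasic spike-wave: fundamental plus
  a half-amplitude second harmonic), scaled relative to the local
  pre-event baseline envelope exactly as the detector defines it, and
  Tukey-windowed waxing-waning spindles scaled in baseline-SD units;
* movement artifacts as simultaneous EMG/EEG bursts during wake.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import fftconvolve, hilbert
from scipy.signal.windows import hann, tukey

from .core import EventInterval, ParameterError, SignalRecord
from .preprocess import FilterSpec, bandpass_array
from .spectral import BANDS

__all__ = [
    "StateParams",
    "EventParams",
    "GeneratorSpec",
    "GroundTruth",
    "sample_state_sequence",
    "synth_signals",
    "inject_events",
    "generate_record",
    "AnimalSpec",
    "make_cohort",
    "realize_animal",
    "swo_protocol_track",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StateParams:
    """Dwell-time and signal parameters of one vigilance state."""

    dwell_mean_s: float
    dwell_sigma: float = 0.6  # log-normal shape
    background_amp_mv: float = 0.04  # 1/f EEG background RMS
    delta_amp_mv: float = 0.0  # 0.5-4 Hz component RMS
    theta_amp_mv: float = 0.0  # 6-10 Hz component RMS
    emg_rms_mv: float = 0.02


@dataclass(frozen=True)
class EventParams:
    """Injection parameters of one event kind."""

    rates_per_hr: dict  # state -> events per hour of that state
    freq_lo_hz: float
    freq_hi_hz: float
    amplitude_mult: float  # vs local baseline envelope (SD units for spindles)
    dur_lo_s: float
    dur_hi_s: float
    bilateral_frac: float = 1.0


def _default_states() -> dict:
    # time fractions roughly wake 40% / NREM 45% / REM 15%, mouse-like
    # fragmentation (dwells around 1-2 min)
    return {
        "wake": StateParams(
            dwell_mean_s=90.0, background_amp_mv=0.05, emg_rms_mv=0.10
        ),
        "NREM": StateParams(
            dwell_mean_s=90.0, background_amp_mv=0.04, delta_amp_mv=0.15,
            emg_rms_mv=0.02,
        ),
        "REM": StateParams(
            dwell_mean_s=75.0, background_amp_mv=0.015, theta_amp_mv=0.06,
            emg_rms_mv=0.008,
        ),
    }


def _default_events() -> dict:
    return {
        "SWD": EventParams(
            rates_per_hr={"wake": 20.0, "NREM": 60.0, "REM": 15.0},
            freq_lo_hz=6.0, freq_hi_hz=12.0, amplitude_mult=3.0,
            dur_lo_s=1.3, dur_hi_s=4.0,
        ),
        "SSWD": EventParams(
            rates_per_hr={"wake": 0.0, "NREM": 10.0, "REM": 0.0},
            freq_lo_hz=3.0, freq_hi_hz=6.0, amplitude_mult=3.0,
            dur_lo_s=1.3, dur_hi_s=3.0,
        ),
        "spindle": EventParams(
            rates_per_hr={"wake": 0.0, "NREM": 40.0, "REM": 0.0},
            freq_lo_hz=10.0, freq_hi_hz=15.0, amplitude_mult=4.0,
            dur_lo_s=0.8, dur_hi_s=2.5,
        ),
    }


#: transition probabilities of the semi-Markov chain
TRANSITIONS = {
    "wake": (("NREM", 1.0),),
    "NREM": (("wake", 0.60), ("REM", 0.40)),
    "REM": (("wake", 0.70), ("NREM", 0.30)),
}


@dataclass
class GeneratorSpec:
    duration_s: float = 3 * 3600.0
    rate: float = 1000.0  # native rate before downsampling to 200 Hz
    seed: int = 0
    state_params: dict = field(default_factory=_default_states)
    event_params: dict = field(default_factory=_default_events)
    artifact_rate_per_hr: float = 2.0
    artifact_dur_s: float = 2.0
    crossfade_s: float = 0.5
    eeg_channel_noise_frac: float = 0.2  # independent noise added per channel
    sex_effect: float = 1.0  # NREM delta amplitude multiplier for F animals
    phase_effect: dict = field(
        default_factory=lambda: {"swd_rate": 1.0, "nrem_dwell": 1.0}
    )

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate <= 0:
            raise ParameterError("duration and rate must be positive")
        for name, sp in self.state_params.items():
            if sp.dwell_mean_s <= 10:
                raise ParameterError(f"{name} dwell mean must exceed 10 s")


@dataclass
class GroundTruth:
    """Exact generator-side labels for every pipeline stage."""

    state_seconds: np.ndarray  # one label per second
    events: list[EventInterval] = field(default_factory=list)
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def epoch_labels(self, epoch_len_s: float = 10.0) -> list[str]:
        """Majority per-epoch true label (for staging accuracy checks)."""
        n_epochs = len(self.state_seconds) // int(epoch_len_s)
        labels = []
        for e in range(n_epochs):
            seg = self.state_seconds[e * 10 : (e + 1) * 10]
            vals, counts = np.unique(seg, return_counts=True)
            labels.append(str(vals[np.argmax(counts)]))
        return labels


def sample_state_sequence(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> GroundTruth:
    """Semi-Markov state track at 1-s resolution."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_sec = int(spec.duration_s)
    track = np.empty(n_sec, dtype="U8")
    t = 0
    state = "wake"
    while t < n_sec:
        sp = spec.state_params[state]
        mean, sigma = sp.dwell_mean_s, sp.dwell_sigma
        mu = np.log(mean) - sigma**2 / 2  # log-normal with the given mean
        dwell = max(10, int(round(rng.lognormal(mu, sigma))))
        track[t : t + dwell] = state
        t += dwell
        options = TRANSITIONS[state]
        names = [o[0] for o in options]
        probs = np.array([o[1] for o in options])
        state = names[rng.choice(len(names), p=probs / probs.sum())]
    return GroundTruth(state_seconds=track, params={"spec": spec})


def _colored_noise(rng: np.random.Generator, n: int, rate: float, exponent: float = 1.0) -> np.ndarray:
    """Unit-RMS noise with power spectrum 1/f**exponent (flat below 0.5 Hz)."""
    white = rng.standard_normal(n)
    spec_w = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    nz = f > 0.5
    shape[nz] = (0.5 / f[nz]) ** (exponent / 2)
    shape[f == 0] = 0.0
    x = np.fft.irfft(spec_w * shape, n)
    return x / np.std(x)


def _band_noise(rng: np.random.Generator, n: int, rate: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (hard FFT mask)."""
    white = rng.standard_normal(n)
    spec_w = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (f >= band[0]) & (f <= band[1])
    x = np.fft.irfft(spec_w * mask, n)
    s = np.std(x)
    return x / s if s > 0 else x


def _smooth_gate(values_per_sec: np.ndarray, rate: float, crossfade_s: float) -> np.ndarray:
    """Per-sample gate from per-second values, crossfaded over ``crossfade_s``."""
    per_sample = np.repeat(values_per_sec, int(round(rate)))
    n_k = max(3, int(round(crossfade_s * rate)))
    kernel = hann(n_k)
    kernel /= kernel.sum()
    return fftconvolve(per_sample, kernel, mode="same")


def synth_signals(
    truth: GroundTruth, spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> SignalRecord:
    """State-conditioned EEG (two correlated channels) and EMG at native rate."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    track = truth.state_seconds
    n_sec = len(track)
    rate = spec.rate
    n = int(n_sec * rate)
    sp = spec.state_params

    bg_amp = np.array([sp[s].background_amp_mv for s in track])
    delta_amp = np.array([sp[s].delta_amp_mv for s in track])
    theta_amp = np.array([sp[s].theta_amp_mv for s in track])
    emg_amp = np.array([sp[s].emg_rms_mv for s in track])

    bg_gate = _smooth_gate(bg_amp, rate, spec.crossfade_s)
    delta_gate = _smooth_gate(delta_amp, rate, spec.crossfade_s)
    theta_gate = _smooth_gate(theta_amp, rate, spec.crossfade_s)
    emg_gate = _smooth_gate(emg_amp, rate, spec.crossfade_s)

    common = (
        bg_gate * _colored_noise(rng, n, rate)
        + delta_gate * _band_noise(rng, n, rate, BANDS["delta_staging"])
        + theta_gate * _band_noise(rng, n, rate, BANDS["theta"])
    )
    frac = spec.eeg_channel_noise_frac
    channels = {}
    for name in ("EEG L", "EEG R"):
        indep = bg_gate * _colored_noise(rng, n, rate)
        channels[name] = common + frac * indep
    channels["EMG"] = emg_gate * rng.standard_normal(n)

    # movement artifacts during wake: simultaneous EMG and broadband EEG bursts
    n_art = rng.poisson(spec.artifact_rate_per_hr * n_sec / 3600.0)
    wake_sec = np.flatnonzero(track == "wake")
    art_intervals: list[tuple[float, float]] = []
    dur = spec.artifact_dur_s
    for _ in range(n_art):
        ok = wake_sec[(wake_sec > 10) & (wake_sec < n_sec - dur - 10)]
        if ok.size == 0:
            break
        t0 = float(rng.choice(ok))
        if any(t0 < b + 5 and a - 5 < t0 + dur for a, b in art_intervals):
            continue
        i, j = int(t0 * rate), int((t0 + dur) * rate)
        w = tukey(j - i, 0.2)
        channels["EMG"][i:j] += 10 * spec.state_params["wake"].emg_rms_mv * w * rng.standard_normal(j - i)
        burst = 6 * spec.state_params["wake"].background_amp_mv * w * rng.standard_normal(j - i)
        for name in ("EEG L", "EEG R"):
            channels[name][i:j] += burst
        art_intervals.append((t0, t0 + dur))
    truth.artifact_intervals = sorted(art_intervals)

    return SignalRecord(
        channels=channels,
        rate=rate,
        roles={"EEG L": "eeg_left", "EEG R": "eeg_right", "EMG": "emg"},
        units={k: "mV" for k in channels},
    )


def _swd_waveform(rng: np.random.Generator, rate: float, dur_s: float, f_hz: float) -> np.ndarray:
    """Stylized spike-wave cycle: fundamental + half-amplitude 2nd harmonic."""
    t = np.arange(int(round(dur_s * rate))) / rate
    phase = rng.uniform(0, 2 * np.pi)
    w = np.sin(2 * np.pi * f_hz * t + phase) + 0.5 * np.sin(4 * np.pi * f_hz * t + phase + np.pi / 4)
    return w * tukey(len(t), 0.15)


def _local_baseline_env(
    x: np.ndarray, rate: float, t0_s: float, band: tuple[float, float], window_s: float = 10.0
) -> float:
    """Median band envelope over the 10 s before ``t0_s`` (detector semantics)."""
    j = int(t0_s * rate)
    i = max(0, j - int(window_s * rate))
    seg = x[i:j]
    env = np.abs(hilbert(bandpass_array(seg, rate, FilterSpec(*band))))
    return float(np.median(env))


def _local_baseline_env_stats(
    x: np.ndarray, rate: float, t0_s: float, band: tuple[float, float], window_s: float = 10.0
) -> tuple[float, float]:
    """(envelope mean, raw band-signal SD) over the 10 s before ``t0_s``."""
    j = int(t0_s * rate)
    i = max(0, j - int(window_s * rate))
    bp = bandpass_array(x[i:j], rate, FilterSpec(*band))
    env = np.abs(hilbert(bp))
    return float(np.mean(env)), float(np.std(bp))


def _state_runs(track: np.ndarray) -> list[tuple[str, int, int]]:
    runs = []
    start = 0
    for i in range(1, len(track) + 1):
        if i == len(track) or track[i] != track[i - 1]:
            runs.append((str(track[start]), start, i))
            start = i
    return runs


def inject_events(
    record: SignalRecord,
    truth: GroundTruth,
    spec: GeneratorSpec,
    rng: np.random.Generator | None = None,
) -> tuple[SignalRecord, GroundTruth]:
    """Add Poisson-placed SWD/SSWD/spindle waveforms; log exact truth.

    Counts per (kind, state) are Poisson with the spec rates; onsets are
    uniform over that state's runs with the event fully inside its run,
    away from artifacts, and non-overlapping (with margin) on a channel.
    Unplaceable events are thinned with a logged warning.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    out = record.copy()
    track = truth.state_seconds
    rate = record.rate
    runs = _state_runs(track)
    margin = 11.0  # keep the preceding baseline window event-free
    occupied: list[tuple[float, float]] = [
        (a - 2, b + 2) for a, b in truth.artifact_intervals
    ]
    ev_truth: list[EventInterval] = []
    names = record.eeg_names

    for kind in ("SWD", "SSWD", "spindle"):
        ep = spec.event_params[kind]
        band = (ep.freq_lo_hz, ep.freq_hi_hz)
        for state in ("wake", "NREM", "REM"):
            rate_hr = ep.rates_per_hr.get(state, 0.0)
            if rate_hr <= 0:
                continue
            state_sec = int(np.sum(track == state))
            n_ev = rng.poisson(rate_hr * state_sec / 3600.0)
            placed = 0
            attempts = 0
            while placed < n_ev and attempts < 50 * max(n_ev, 1):
                attempts += 1
                dur = float(rng.uniform(ep.dur_lo_s, ep.dur_hi_s))
                eligible = [
                    (s0, s1) for st, s0, s1 in runs
                    if st == state and (s1 - s0) > dur + margin + 2
                ]
                if not eligible:
                    break
                lens = np.array([s1 - s0 - dur - margin - 2 for s0, s1 in eligible])
                pick = rng.choice(len(eligible), p=lens / lens.sum())
                s0, s1 = eligible[pick]
                t0 = float(rng.uniform(s0 + margin, s1 - dur - 2))
                if any(t0 - margin < b and a < t0 + dur + 2 for a, b in occupied):
                    continue
                f_hz = float(rng.uniform(ep.freq_lo_hz, ep.freq_hi_hz))
                bilateral = bool(rng.random() < ep.bilateral_frac)
                side = "bilateral" if bilateral else ("left" if rng.random() < 0.5 else "right")
                targets = names if bilateral else ((names[0],) if side == "left" else (names[1],))
                i = int(round(t0 * rate))
                if kind == "spindle":
                    t = np.arange(int(round(dur * rate))) / rate
                    wave_shape = np.sin(2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi))
                    wave_shape *= tukey(len(t), 0.5)
                else:
                    wave_shape = _swd_waveform(rng, rate, dur, f_hz)
                for name in targets:
                    x = out.channels[name]
                    if kind == "spindle":
                        mean, sd = _local_baseline_env_stats(x, rate, t0, band)
                        amp = mean + ep.amplitude_mult * sd
                    else:
                        base_band = (
                            BANDS["delta_staging"] if state == "NREM" else BANDS["total"]
                        )
                        amp = ep.amplitude_mult * _local_baseline_env(x, rate, t0, base_band)
                    x[i : i + len(wave_shape)] += amp * wave_shape
                occupied.append((t0 - 1, t0 + dur + 1))
                ev_truth.append(
                    EventInterval(
                        onset_s=t0,
                        offset_s=t0 + dur,
                        kind=kind,
                        band_lo_hz=band[0],
                        band_hi_hz=band[1],
                        peak_freq_hz=f_hz,
                        laterality=side,
                        state=state,
                        channel_roles=tuple(record.roles[n] for n in targets),
                    )
                )
                placed += 1
            if placed < n_ev:
                logger.warning(
                    "thinned %s/%s %s events in %s (placement constraints)",
                    n_ev - placed, n_ev, kind, state,
                )
    ev_truth.sort(key=lambda e: e.onset_s)
    truth.events = ev_truth
    return out, truth


def generate_record(spec: GeneratorSpec) -> tuple[SignalRecord, GroundTruth]:
    """State track + signals + injected events from one seed."""
    rng = np.random.default_rng(spec.seed)
    truth = sample_state_sequence(spec, rng)
    record = synth_signals(truth, spec, rng)
    record, truth = inject_events(record, truth, spec, rng)
    record.artifact_mask = list(truth.artifact_intervals)
    return record, truth


@dataclass(frozen=True)
class AnimalSpec:
    """Lightweight handle for one animal x phase; realized on demand."""

    animal_id: str
    genotype: str
    sex: str
    phase: str
    spec: GeneratorSpec


def make_cohort(
    design: Sequence[dict],
    base_spec: GeneratorSpec,
    seed: int,
    random_effect_sigma: float = 0.25,
) -> list[AnimalSpec]:
    """Per-animal generator specs for a cohort design.

    ``design`` entries: ``{"genotype": "het", "sex": "F", "n": 6,
    "phases": ["pre", "post"]}``. Each animal gets log-normal random
    effects (shared across its phases) on SWD rates; group F gets the
    spec's ``sex_effect`` multiplier on NREM delta amplitude; ``post``
    phases get the spec's ``phase_effect`` multipliers on SWD rates and
    NREM dwell. All effect sizes are recorded in each AnimalSpec's spec.
    """
    rng = np.random.default_rng(seed)
    out: list[AnimalSpec] = []
    idx = 0
    for cell in design:
        for _ in range(int(cell["n"])):
            idx += 1
            animal_id = f"{cell['genotype']}_{cell['sex']}_{idx:03d}"
            re_rate = float(rng.lognormal(0.0, random_effect_sigma))
            animal_seed = int(rng.integers(0, 2**31 - 1))
            for phase in cell.get("phases", ["baseline"]):
                sp = base_spec
                states = dict(sp.state_params)
                events = {k: replace(v) for k, v in sp.event_params.items()}
                rate_mult = re_rate
                dwell_mult = 1.0
                if phase == "post":
                    rate_mult *= sp.phase_effect.get("swd_rate", 1.0)
                    dwell_mult = sp.phase_effect.get("nrem_dwell", 1.0)
                for kind in ("SWD", "SSWD"):
                    ep = events[kind]
                    events[kind] = replace(
                        ep,
                        rates_per_hr={s: r * rate_mult for s, r in ep.rates_per_hr.items()},
                    )
                if cell["sex"] == "F":
                    states["NREM"] = replace(
                        states["NREM"],
                        delta_amp_mv=states["NREM"].delta_amp_mv * sp.sex_effect,
                    )
                if dwell_mult != 1.0:
                    states["NREM"] = replace(
                        states["NREM"],
                        dwell_mean_s=states["NREM"].dwell_mean_s * dwell_mult,
                    )
                phase_seed = animal_seed + (0 if phase in ("baseline", "pre") else 1)
                out.append(
                    AnimalSpec(
                        animal_id=animal_id,
                        genotype=cell["genotype"],
                        sex=cell["sex"],
                        phase=phase,
                        spec=replace(
                            sp, seed=phase_seed, state_params=states, event_params=events
                        ),
                    )
                )
    return out


def realize_animal(aspec: AnimalSpec) -> tuple[SignalRecord, GroundTruth]:
    return generate_record(aspec.spec)


@dataclass
class SwoProtocol:
    """Optogenetic slow-wave-oscillation induction timing."""

    laser_intervals: list[tuple[float, float]]  # laser-on (down-state) spans
    pulse_times: list[float]  # intracortical pulses at up-state starts
    pulse_s: float

    @property
    def n_cycles(self) -> int:
        return len(self.laser_intervals)


def swo_protocol_track(
    duration_s: float = 600.0,
    period_s: float = 2.0,
    down_s: float = 1.8,
    up_s: float = 0.2,
    pulse_s: float = 0.02,
) -> SwoProtocol:
    """Laser/pulse timing for SWO induction (0.5 Hz: 1.8 s down, 0.2 s up).

    Each cycle is laser-on for ``down_s`` then laser-off for ``up_s`` with
    an electrical pulse in the first ``pulse_s`` of the up-state. Defaults
    give 300 cycles and 300 pulses over 10 min.
    """
    if abs(down_s + up_s - period_s) > 1e-9:
        raise ParameterError(
            f"down_s + up_s = {down_s + up_s} must equal period_s = {period_s}"
        )
    n_cycles = int(duration_s // period_s)
    laser = [(k * period_s, k * period_s + down_s) for k in range(n_cycles)]
    pulses = [k * period_s + down_s for k in range(n_cycles)]
    return SwoProtocol(laser_intervals=laser, pulse_times=pulses, pulse_s=pulse_s)
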