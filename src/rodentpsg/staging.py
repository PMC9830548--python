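"""Vigilance-state staging on 10-s epochs with a >5 s dominance rule.

Criteria follow standard rodent polysomnography: wake has low-amplitude EEG
with high EMG tone; NREM has high-amplitude EEG dominated by delta
(<4 Hz); REM has uniform low-amplitude EEG with dominant theta (6-10 Hz)
and muscle atonia. Because the qualitative criteria need numbers to run,
thresholds are calibrated per record (EMG bimodal split, EEG envelope
median) with fixed delta-fraction and theta/delta cuts, all overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Hypnogram, InputError, SignalRecord
from .preprocess import FilterSpec, bandpass_array
from .spectral import BANDS

__all__ = [
    "StagingThresholds",
    "StateMetrics",
    "EpochFeatures",
    "compute_epoch_features",
    "calibrate_thresholds",
    "score_epochs",
    "summarize_states",
    "CalibrationError",
]

EPOCH_LEN_S = 10.0
SUB_EPOCH_S = 1.0

#: default fixed cuts (config-overridable)
DELTA_FRAC_CUT = 0.5
THETA_RATIO_CUT = 1.5


class CalibrationError(ValueError):
    """Features are degenerate; no thresholds can be derived."""


@dataclass(frozen=True)
class StagingThresholds:
    emg_wake_cut: float
    eeg_amp_cut: float
    delta_frac_cut: float = DELTA_FRAC_CUT
    theta_ratio_cut: float = THETA_RATIO_CUT

    def __post_init__(self) -> None:
        for name in ("emg_wake_cut", "eeg_amp_cut", "delta_frac_cut", "theta_ratio_cut"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InputError(f"threshold {name} must be finite and positive, got {v}")


@dataclass
class EpochFeatures:
    """Per-second features plus their 10-s epoch aggregation."""

    sub: pd.DataFrame  # index: second; columns below
    epoch: pd.DataFrame  # index: epoch_index; means of sub features

    COLUMNS = (
        "eeg_rms",
        "delta_pow",
        "theta_pow",
        "total_pow",
        "delta_frac",
        "theta_delta",
        "emg_rms",
        "artifact",
    )


def _per_second(x: np.ndarray, rate: float, n_sec: int, stat: str) -> np.ndarray:
    n = int(round(rate))
    x = x[: n_sec * n].reshape(n_sec, n)
    if stat == "ms":
        return np.mean(x**2, axis=1)
    return np.sqrt(np.mean(x**2, axis=1))


def compute_epoch_features(record: SignalRecord) -> EpochFeatures:
    """Band powers, envelope RMS, and EMG tone per 1-s sub-epoch.

    EEG features are averaged over the two EEG channels. Band powers are
    per-second mean squares of zero-phase band-passed signals (delta
    0.5-4 Hz, theta 6-10 Hz, total 0.5-30 Hz).
    """
    if record.duration_s < EPOCH_LEN_S:
        raise InputError("record shorter than one 10-s epoch")
    n_sec = int(record.duration_s)  # whole seconds
    rate = record.rate
    eeg_names = record.eeg_names
    feats = {c: np.zeros(n_sec) for c in ("eeg_rms", "delta_pow", "theta_pow", "total_pow")}
    for name in eeg_names:
        x = record.channels[name]
        broad = bandpass_array(x, rate, FilterSpec(*BANDS["total"]))
        feats["eeg_rms"] += _per_second(broad, rate, n_sec, "rms")
        for key, band in (
            ("delta_pow", BANDS["delta_staging"]),
            ("theta_pow", BANDS["theta"]),
        ):
            feats[key] += _per_second(bandpass_array(x, rate, FilterSpec(*band)), rate, n_sec, "ms")
        feats["total_pow"] += _per_second(broad, rate, n_sec, "ms")
    for key in feats:
        feats[key] /= len(eeg_names)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_frac = np.where(feats["total_pow"] > 0, feats["delta_pow"] / feats["total_pow"], 0.0)
        theta_delta = np.where(feats["delta_pow"] > 0, feats["theta_pow"] / feats["delta_pow"], 0.0)
    emg = record.channels[record.emg_name]
    emg_rms = _per_second(emg, rate, n_sec, "rms")
    art_mask = np.zeros(n_sec, dtype=bool)
    for a, b in record.artifact_mask:
        art_mask[int(a) : min(n_sec, int(np.ceil(b)))] = True
    sub = pd.DataFrame(
        {
            "eeg_rms": feats["eeg_rms"],
            "delta_pow": feats["delta_pow"],
            "theta_pow": feats["theta_pow"],
            "total_pow": feats["total_pow"],
            "delta_frac": delta_frac,
            "theta_delta": theta_delta,
            "emg_rms": emg_rms,
            "artifact": art_mask,
        }
    )
    sub.index.name = "second"
    epoch_idx = sub.index // int(EPOCH_LEN_S)
    n_epochs = int(record.duration_s // EPOCH_LEN_S)
    grouped = sub.groupby(epoch_idx).mean(numeric_only=False)
    epoch = grouped.loc[grouped.index < n_epochs]
    epoch.index.name = "epoch_index"
    return EpochFeatures(sub=sub, epoch=epoch)


def _two_means_split(values: np.ndarray) -> tuple[float, bool]:
    """Deterministic 1-D 2-means; returns (midpoint of means, well-separated)."""
    lo, hi = np.percentile(values, [25, 75])
    c = np.array([lo, hi], dtype=float)
    assign = np.zeros(len(values), dtype=int)
    for _ in range(100):
        assign = np.abs(values[:, None] - c[None, :]).argmin(axis=1)
        new = np.array(
            [values[assign == k].mean() if (assign == k).any() else c[k] for k in (0, 1)]
        )
        if np.allclose(new, c):
            break
        c = new
    order = np.argsort(c)
    c = c[order]
    resid = np.concatenate(
        [(values[assign == order[k]] - c[k]) ** 2 for k in (0, 1) if (assign == order[k]).any()]
    )
    within = float(np.sqrt(resid.mean()))
    sep = (c[1] - c[0]) > 1.5 * within if within > 0 else True
    return float(c.mean()), bool(sep)


def calibrate_thresholds(
    features: EpochFeatures,
    delta_frac_cut: float = DELTA_FRAC_CUT,
    theta_ratio_cut: float = THETA_RATIO_CUT,
) -> StagingThresholds:
    """Data-driven per-record cuts.

    The EMG wake cut is the midpoint between the two modes of log EMG RMS
    (fallback: 60th percentile if the split is not bimodal); the EEG
    amplitude cut is the median envelope RMS. Requires >= 30 min of data.
    """
    if len(features.sub) < 1800:
        raise InputError(f"need >= 30 min of features, got {len(features.sub)} s")
    sub = features.sub.loc[~features.sub["artifact"]]
    emg = sub["emg_rms"].to_numpy()
    eeg = sub["eeg_rms"].to_numpy()
    if np.ptp(emg) == 0 or np.ptp(eeg) == 0:
        raise CalibrationError("constant features; cannot calibrate thresholds")
    log_emg = np.log(np.maximum(emg, 1e-12))
    mid, ok = _two_means_split(log_emg)
    emg_cut = float(np.exp(mid)) if ok else float(np.percentile(emg, 60))
    return StagingThresholds(
        emg_wake_cut=emg_cut,
        eeg_amp_cut=float(np.median(eeg)),
        delta_frac_cut=delta_frac_cut,
        theta_ratio_cut=theta_ratio_cut,
    )


def _label_sub_epochs(sub: pd.DataFrame, th: StagingThresholds) -> np.ndarray:
    emg = sub["emg_rms"].to_numpy()
    eeg = sub["eeg_rms"].to_numpy()
    dfrac = sub["delta_frac"].to_numpy()
    tratio = sub["theta_delta"].to_numpy()
    labels = np.empty(len(sub), dtype="U8")
    wake = emg > th.emg_wake_cut
    nrem = ~wake & (dfrac > th.delta_frac_cut) & (eeg > th.eeg_amp_cut)
    rem = ~wake & ~nrem & (tratio > th.theta_ratio_cut) & (eeg <= th.eeg_amp_cut)
    labels[wake] = "wake"
    labels[nrem] = "NREM"
    labels[rem] = "REM"
    rest = ~(wake | nrem | rem)
    if rest.any():
        # nearest-matching state by normalized shortfall from each cut
        d_wake = np.clip((th.emg_wake_cut - emg) / th.emg_wake_cut, 0, None)
        d_nrem = np.maximum(
            np.clip((th.delta_frac_cut - dfrac) / th.delta_frac_cut, 0, None),
            np.clip((th.eeg_amp_cut - eeg) / th.eeg_amp_cut, 0, None),
        )
        d_rem = np.maximum(
            np.clip((th.theta_ratio_cut - tratio) / th.theta_ratio_cut, 0, None),
            np.clip((eeg - th.eeg_amp_cut) / th.eeg_amp_cut, 0, None),
        )
        dist = np.vstack([d_wake, d_nrem, d_rem])
        pick = dist[:, rest].argmin(axis=0)
        labels[rest] = np.array(["wake", "NREM", "REM"])[pick]
    return labels


def score_epochs(features: EpochFeatures, thresholds: StagingThresholds) -> Hypnogram:
    """Label sub-epochs by the decision rule, then apply epoch dominance.

    An epoch takes the state occupying more than 5 of its 10 seconds; a
    5 s/5 s tie inherits the previous epoch's state (hysteresis). Epochs
    more than 50% artifact-masked are labeled ``artifact``.
    """
    sub_labels = _label_sub_epochs(features.sub, thresholds)
    art = features.sub["artifact"].to_numpy(dtype=bool)
    n_epochs = len(sub_labels) // int(EPOCH_LEN_S)
    labels: list[str] = []
    order = ("wake", "NREM", "REM")
    for e in range(n_epochs):
        sl = slice(e * 10, (e + 1) * 10)
        if art[sl].sum() > 5:
            labels.append("artifact")
            continue
        seg = sub_labels[sl][~art[sl]]
        counts = {s: int(np.sum(seg == s)) for s in order}
        best = max(counts.values())
        winners = [s for s in order if counts[s] == best]
        if best > 5 or len(winners) == 1:
            labels.append(winners[0])
        else:
            prev = next((l for l in reversed(labels) if l != "artifact"), None)
            labels.append(prev if prev in winners else winners[0])
    return Hypnogram(labels=labels, sub_labels=sub_labels, epoch_len_s=EPOCH_LEN_S)


@dataclass
class StateMetrics:
    """Durations, bout counts, and transition counts from a hypnogram."""

    duration_s: dict[str, float] = field(default_factory=dict)
    bout_count: dict[str, int] = field(default_factory=dict)
    transition_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    artifact_s: float = 0.0

    @property
    def total_s(self) -> float:
        return sum(self.duration_s.values()) + self.artifact_s


def summarize_states(hyp: Hypnogram) -> StateMetrics:
    """Durations (epochs x 10 s), bouts (maximal runs), transitions.

    Transitions are counted between consecutive non-artifact epochs with
    differing labels; an artifact epoch terminates a bout and contributes
    no transition.
    """
    m = StateMetrics(
        duration_s={s: 0.0 for s in ("wake", "NREM", "REM")},
        bout_count={s: 0 for s in ("wake", "NREM", "REM")},
    )
    prev: str | None = None
    prev_nonart: str | None = None
    for lab in hyp.labels:
        if lab == "artifact":
            m.artifact_s += hyp.epoch_len_s
            prev = None
            continue
        m.duration_s[lab] += hyp.epoch_len_s
        if lab != prev:
            m.bout_count[lab] += 1
        if prev_nonart is not None and prev_nonart != lab and prev is not None:
            key = (prev_nonart, lab)
            m.transition_counts[key] = m.transition_counts.get(key, 0) + 1
        prev = lab
        prev_nonart = lab
    return m
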