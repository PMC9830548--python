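"""Band filtering, resampling to the analysis rate, and artifact masking.

Acquisition bands follow standard rodent EEG practice (EEG 0.1-100 Hz,
EMG 0.1-400 Hz); all quantitative analysis runs at 200 Hz. Motor artifacts
are flagged from EMG power because these recordings carry no video channel:
a 1-s EMG RMS trace is thresholded at median + k robust SDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import ParameterError, SignalRecord, normalize_intervals

__all__ = ["FilterSpec", "bandpass", "resample_to", "mask_artifacts", "ANALYSIS_RATE_HZ"]

#: common analysis sampling rate (Hz) after downsampling
ANALYSIS_RATE_HZ = 200.0

#: default acquisition bands (Hz)
EEG_BAND = (0.1, 100.0)
EMG_BAND = (0.1, 400.0)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase band-pass: Butterworth high-pass + low-pass cascade."""

    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ParameterError(f"invalid band [{self.low_hz}, {self.high_hz}] Hz")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")

    def sos(self, rate: float) -> np.ndarray:
        nyq = rate / 2
        if self.high_hz >= nyq:
            raise ParameterError(
                f"band edge {self.high_hz} Hz >= Nyquist {nyq} Hz at rate {rate}"
            )
        # Cascade instead of a single band-pass design: a 0.1 Hz edge next to
        # a 100 Hz edge makes the normalized band-pass numerically fragile.
        sections = [signal.butter(self.order, self.high_hz / nyq, "low", output="sos")]
        if self.low_hz > 0:
            sections.insert(
                0, signal.butter(self.order, self.low_hz / nyq, "high", output="sos")
            )
        return np.vstack(sections)


def bandpass_array(x: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Forward-backward (zero-phase) band-pass of one signal vector.

    The filtfilt pad length scales with the low corner's time constant: a
    sub-hertz high-pass settles over seconds, and scipy's default padding
    leaves edge transients that contaminate the whole segment.
    """
    x = np.asarray(x, dtype=float)
    padlen = None
    if spec.low_hz > 0:
        padlen = min(x.size - 1, int(round(3.0 * rate / spec.low_hz)))
    return signal.sosfiltfilt(spec.sos(rate), x, padlen=padlen)


def bandpass(record: SignalRecord, role: str, spec: FilterSpec) -> SignalRecord:
    """Apply a zero-phase band-pass to the channel holding ``role`` only."""
    out = record.copy()
    name = record.channel_for(role)
    out.channels[name] = bandpass_array(record.channels[name], record.rate, spec)
    return out


def resample_to(record: SignalRecord, target_rate: float = ANALYSIS_RATE_HZ) -> SignalRecord:
    """Polyphase anti-aliased resampling of every channel to ``target_rate``."""
    if target_rate > record.rate:
        raise ParameterError(
            f"target rate {target_rate} Hz exceeds native rate {record.rate} Hz"
        )
    if target_rate == record.rate:
        return record.copy()
    frac = Fraction(target_rate / record.rate).limit_denominator(10000)
    channels = {
        name: signal.resample_poly(x, frac.numerator, frac.denominator)
        for name, x in record.channels.items()
    }
    return SignalRecord(
        channels=channels,
        rate=float(target_rate),
        roles=dict(record.roles),
        units=dict(record.units),
        start_time=record.start_time,
        artifact_mask=list(record.artifact_mask),  # mask is in seconds
    )


def _block_rms(x: np.ndarray, rate: float, block_s: float = 1.0) -> np.ndarray:
    n_block = int(round(block_s * rate))
    n = len(x) // n_block
    if n == 0:
        return np.array([])
    return np.sqrt(np.mean(x[: n * n_block].reshape(n, n_block) ** 2, axis=1))


def mask_artifacts(
    record: SignalRecord,
    k_sd: float = 5.0,
    min_dur_s: float = 0.5,
    merge_gap_s: float = 1.0,
) -> SignalRecord:
    """Flag movement artifacts from EMG power.

    Seconds where the 1-s EMG RMS exceeds ``median + k_sd * 1.4826 * MAD``
    for at least ``min_dur_s`` are added to the artifact mask; intervals
    closer than ``merge_gap_s`` are merged. Re-running with the same
    parameters reproduces the same mask (the statistic is computed on the
    unmodified signal), so masking is idempotent.
    """
    emg = record.channels[record.emg_name]
    rms = _block_rms(emg, record.rate, 1.0)
    if rms.size == 0:
        return record.copy()
    # EMG tone is bimodal (wake vs sleep atonia); movement artifacts sit on
    # top of the wake mode. When a substantial high-tone mode exists, anchor
    # the threshold on it so normal wake tone is never flagged wholesale.
    ref = rms
    log_rms = np.log(np.maximum(rms, 1e-12))
    med_l = np.median(log_rms)
    upper = rms[log_rms > med_l + np.log(2.0)]
    if upper.size >= 0.1 * rms.size:
        ref = upper
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        # flat EMG: fall back to ordinary SD so a literally constant trace
        # (SD 0) yields no artifacts rather than flagging everything
        robust_sd = float(np.std(ref))
    cut = med + k_sd * robust_sd
    above = rms > cut if robust_sd > 0 else np.zeros_like(rms, dtype=bool)
    intervals = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            if (j - i) * 1.0 >= min_dur_s:
                intervals.append((float(i), float(j)))
            i = j
        else:
            i += 1
    out = record.copy()
    if intervals:
        out.artifact_mask = normalize_intervals(
            list(out.artifact_mask) + intervals, merge_gap_s=merge_gap_s
        )
    return out
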