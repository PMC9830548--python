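"""Multitaper spectral estimation and the NREM delta-power statistic.

PSDs are estimated with DPSS (Slepian) tapers, averaging the eigenspectra,
and normalized one-sided so that ``sum(psd) * df`` equals the biased
variance estimate of the segment (Parseval). Defaults ``nw=4`` with 7
tapers suit 10-s EEG windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .core import Hypnogram, InputError, ParameterError, SignalRecord, SpectralEstimate

__all__ = [
    "BANDS",
    "multitaper_psd",
    "spectrogram",
    "Spectrogram",
    "nrem_delta_power",
]

#: frequency bands (Hz) used across the pipeline
BANDS = {
    "delta_power": (0.1, 4.0),  # NREM delta-power statistic
    "delta_staging": (0.5, 4.0),  # staging / NREM baseline envelope
    "theta": (6.0, 10.0),
    "total": (0.5, 30.0),
    "swd": (6.0, 12.0),
    "sswd": (3.0, 6.0),
    "spindle": (10.0, 15.0),
}

DEFAULT_NW = 4.0
DEFAULT_N_TAPERS = 7


def multitaper_psd(
    segment: np.ndarray,
    rate: float,
    nw: float = DEFAULT_NW,
    n_tapers: int = DEFAULT_N_TAPERS,
) -> SpectralEstimate:
    """One-sided multitaper PSD of a single segment.

    Tapers are unit-energy DPSS sequences; the returned density integrates
    (rectangle rule, ``sum(psd)*df``) to the segment's biased variance.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        raise InputError("segment must be 1-D")
    n = x.size
    if n < rate:
        raise InputError(f"segment must be at least 1 s ({n} samples < rate {rate})")
    if n_tapers > 2 * nw - 1:
        raise ParameterError(f"n_tapers={n_tapers} exceeds 2*nw-1={2 * nw - 1:g}")
    tapers = dpss(n, nw, Kmax=n_tapers)  # rows are unit-energy tapers
    spectra = np.abs(rfft(tapers * x[None, :], axis=1)) ** 2
    psd = spectra.mean(axis=0) / rate
    # one-sided: double all bins except DC (and Nyquist when n is even)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = rfftfreq(n, d=1.0 / rate)
    return SpectralEstimate(
        freqs=freqs, psd=psd, window_s=n / rate, nw=nw, n_tapers=n_tapers
    )


@dataclass
class Spectrogram:
    """Windowed multitaper power with per-window artifact flags."""

    times_s: np.ndarray  # window start times
    freqs: np.ndarray
    power: np.ndarray  # (n_windows, n_freqs)
    artifact: np.ndarray  # bool per window
    window_s: float

    def clean_mean(self) -> np.ndarray:
        """Mean PSD over artifact-free windows."""
        ok = ~self.artifact
        if not ok.any():
            raise InputError("all windows are artifact-flagged")
        return self.power[ok].mean(axis=0)


def _window_overlaps(a: float, b: float, intervals) -> bool:
    return any(a < hi and lo < b for lo, hi in intervals)


def spectrogram(
    record: SignalRecord,
    role: str,
    window_s: float = 10.0,
    step_s: float = 10.0,
    nw: float = DEFAULT_NW,
    n_tapers: int = DEFAULT_N_TAPERS,
    max_freq_hz: float | None = None,
) -> Spectrogram:
    """Per-window multitaper PSD of one channel.

    Windows that overlap the artifact mask are flagged and excluded from
    any averaging done downstream.
    """
    x = record.channels[record.channel_for(role)]
    n_win = int(round(window_s * record.rate))
    step = int(round(step_s * record.rate))
    if len(x) < n_win:
        raise InputError("record shorter than one analysis window")
    starts = range(0, len(x) - n_win + 1, step)
    rows, flags, times = [], [], []
    freqs = None
    for s in starts:
        est = multitaper_psd(x[s : s + n_win], record.rate, nw, n_tapers)
        if freqs is None:
            freqs = est.freqs
        t0 = s / record.rate
        rows.append(est.psd)
        times.append(t0)
        flags.append(_window_overlaps(t0, t0 + window_s, record.artifact_mask))
    power = np.asarray(rows)
    freqs = np.asarray(freqs)
    if max_freq_hz is not None:
        sel = freqs <= max_freq_hz
        freqs, power = freqs[sel], power[:, sel]
    return Spectrogram(
        times_s=np.asarray(times),
        freqs=freqs,
        power=power,
        artifact=np.asarray(flags, dtype=bool),
        window_s=window_s,
    )


def nrem_delta_power(
    record: SignalRecord,
    hyp: Hypnogram,
    band: tuple[float, float] = BANDS["delta_power"],
    total_s: float = 1800.0,
    window_s: float = 10.0,
    nw: float = DEFAULT_NW,
    n_tapers: int = DEFAULT_N_TAPERS,
) -> float:
    """NREM delta power (mV^2/Hz): band-average PSD over NREM windows.

    Takes the first ``total_s`` seconds of NREM-labeled, artifact-free
    10-s windows in record order (NREM is fragmented, so the windows need
    not be contiguous in wall-clock time), averages each window's PSD over
    the two EEG channels, band-averages over ``band``, and means across
    windows. Wake and REM windows never contribute.
    """
    need = int(round(total_s / window_s))
    eeg_l, eeg_r = record.eeg_names
    n_win = int(round(window_s * record.rate))
    lo, hi = band
    used = 0
    acc = 0.0
    for i, lab in enumerate(hyp.labels):
        if lab != "NREM":
            continue
        t0 = i * hyp.epoch_len_s
        if _window_overlaps(t0, t0 + window_s, record.artifact_mask):
            continue
        s = int(round(t0 * record.rate))
        if s + n_win > record.n_samples:
            break
        vals = []
        for name in (eeg_l, eeg_r):
            est = multitaper_psd(record.channels[name][s : s + n_win], record.rate, nw, n_tapers)
            vals.append(est.band_power(lo, hi))
        acc += float(np.mean(vals))
        used += 1
        if used >= need:
            break
    if used < need:
        raise InputError(
            f"insufficient NREM: need {total_s:.0f} s, only {used * window_s:.0f} s "
            "of artifact-free NREM windows available"
        )
    return acc / used
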