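"""Spike-wave discharge (SWD/SSWD) and sleep-spindle detection.

Detection criteria:

* SWD: 6-12 Hz trains longer than 1 s whose envelope exceeds 2x the
  preceding baseline amplitude in wake/REM, or 1.5x the preceding
  delta-band (0.5-4 Hz) amplitude in NREM (NREM delta is large, so the
  multiplier is lower and the baseline is delta-conditioned).
* SSWD: the same rule in the 3-6 Hz band (atypical absence discharges).
* Spindle: 10-15 Hz events whose envelope exceeds the preceding baseline
  mean + 1.5 baseline SD, lasting 0.5-5 s; spans claimed by an SWD are
  discarded.

"Amplitude" is the magnitude of the analytic (Hilbert) signal of the
band-passed trace. Baselines are medians (mean/SD for spindles) over the
preceding 10 s of same-state, artifact-free, event-free signal, expanding
the lookback to at most 60 s when needed. Onsets/offsets are refined to
the broadband baseline crossings bounding the suprathreshold run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import hilbert

from .core import EventInterval, Hypnogram, InputError, SignalRecord
from .preprocess import FilterSpec, bandpass_array
from .spectral import BANDS, multitaper_psd

__all__ = [
    "BaselineEstimate",
    "estimate_baseline",
    "detect_band_events",
    "refine_onset_offset",
    "classify_laterality",
    "detect_swd",
    "detect_spindles",
    "assign_state",
]

logger = logging.getLogger(__name__)

#: amplitude multipliers vs baseline for discharge detection
SWD_MULT_WAKE_REM = 2.0
SWD_MULT_NREM = 1.5
SPINDLE_SD_MULT = 1.5

#: default gap bridged between suprathreshold runs of one discharge
MERGE_GAP_S = 0.3

BASELINE_WINDOW_S = 10.0
BASELINE_MAX_LOOKBACK_S = 60.0


@dataclass(frozen=True)
class BaselineEstimate:
    """State-conditioned pre-event amplitude estimate."""

    value: float  # median envelope (mV)
    window_s: float
    band: tuple[float, float]
    state: str
    sd: float = 0.0  # envelope SD over the window (used by spindles)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InputError("baseline amplitude must be non-negative")


def band_envelope(x: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    """Magnitude of the analytic signal of the band-passed trace."""
    return np.abs(hilbert(bandpass_array(x, rate, FilterSpec(*band))))


#: corner-frequency padding of the detection filter (fraction of each edge).
#: A 4th-order Butterworth is 3 dB down at its corners, so an oscillation at
#: a nominal band edge would present ~0.71x its true amplitude and slip under
#: the threshold; padding the corners keeps gain ~1 across the nominal band.
#: Band membership is still decided inside the nominal band (peak frequency).
DETECTION_BAND_PAD = 0.15


def _detection_band(band: tuple[float, float]) -> tuple[float, float]:
    return (band[0] * (1 - DETECTION_BAND_PAD), band[1] * (1 + DETECTION_BAND_PAD))


def _second_labels(hyp: Hypnogram, n_sec: int) -> np.ndarray:
    """Smoothed per-second state track for detection conditioning.

    Starts from the 1-s sub-labels (which track state boundaries inside
    epochs) and absorbs runs shorter than 6 s whose two flanks agree: an
    ongoing discharge distorts the 1-s features under itself, flipping a
    few seconds to a spurious state, while genuine state episodes last
    tens of seconds.
    """
    out = np.full(n_sec, "wake", dtype="U8")
    sub = hyp.sub_labels[:n_sec]
    out[: len(sub)] = sub
    if len(sub) and len(sub) < n_sec:
        out[len(sub):] = sub[-1]
    for _ in range(3):  # a few passes settle nested short runs
        changed = False
        runs = []
        start = 0
        for i in range(1, n_sec + 1):
            if i == n_sec or out[i] != out[i - 1]:
                runs.append((start, i))
                start = i
        for k, (a, b) in enumerate(runs):
            if b - a >= 6 or k == 0 or k == len(runs) - 1:
                continue
            left = out[runs[k - 1][0]]
            right = out[runs[k + 1][0]]
            if left == right and left != out[a]:
                out[a:b] = left
                changed = True
        if not changed:
            break
    return out


def _eligible_lookback_blocks(
    t_block: int,
    state_of_block: np.ndarray,
    excluded: np.ndarray,
    want_blocks: int,
    max_back: int,
) -> list[int]:
    """Indices of preceding same-state, non-excluded 1-s blocks (nearest first)."""
    state = state_of_block[t_block]
    picked: list[int] = []
    for b in range(t_block - 1, max(-1, t_block - 1 - max_back), -1):
        if state_of_block[b] == state and not excluded[b]:
            picked.append(b)
            if len(picked) >= want_blocks:
                break
    return picked


def estimate_baseline(
    channel_signal: np.ndarray,
    rate: float,
    t_s: float,
    hyp: Hypnogram,
    kind: str,
    excluded_seconds: np.ndarray | None = None,
    window_s: float = BASELINE_WINDOW_S,
    max_lookback_s: float = BASELINE_MAX_LOOKBACK_S,
) -> BaselineEstimate | None:
    """Baseline amplitude preceding time ``t_s`` for one candidate.

    For NREM comparisons the envelope is delta-band (0.5-4 Hz); for
    wake/REM it is broadband (0.5-30 Hz). Returns None (candidate must be
    rejected) when no eligible same-state window exists within the
    lookback; the rejection is logged.
    """
    n_sec = int(len(channel_signal) // rate)
    labels = _second_labels(hyp, n_sec)
    state = hyp.state_at(t_s)
    band = BANDS["delta_staging"] if state == "NREM" else BANDS["total"]
    if kind == "spindle":
        band = BANDS["spindle"]
    env = band_envelope(channel_signal, rate, band)
    excl = excluded_seconds if excluded_seconds is not None else np.zeros(n_sec, bool)
    blocks = _eligible_lookback_blocks(
        min(int(t_s), n_sec - 1), labels, excl, int(window_s), int(max_lookback_s)
    )
    if not blocks:
        logger.info("no eligible baseline window before t=%.1f s (state %s)", t_s, state)
        return None
    n = int(round(rate))
    samples = np.concatenate([env[b * n : (b + 1) * n] for b in blocks])
    return BaselineEstimate(
        value=float(np.median(samples)),
        window_s=float(len(blocks)),
        band=band,
        state=state,
        sd=float(np.std(samples)),
    )


def detect_band_events(
    channel_signal: np.ndarray,
    rate: float,
    band: tuple[float, float],
    threshold_mult: float,
    baseline_fn: Callable[[int], float] | np.ndarray | float,
    min_dur_s: float,
    merge_gap_s: float = MERGE_GAP_S,
    max_dur_s: float | None = None,
    strict_min: bool = True,
    artifact_mask: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Threshold the band envelope against a baseline; return candidate spans.

    ``baseline_fn`` may be a scalar, a per-sample array, or a callable of
    the sample index. Samples with non-finite baseline never trigger.
    Suprathreshold runs separated by less than ``merge_gap_s`` are merged;
    runs shorter than ``min_dur_s`` (strictly, when ``strict_min``) or
    longer than ``max_dur_s`` are dropped, as are runs overlapping the
    artifact mask.
    """
    env = band_envelope(channel_signal, rate, band)
    n = env.size
    if callable(baseline_fn):
        base = np.fromiter((baseline_fn(i) for i in range(n)), dtype=float, count=n)
    else:
        base = np.broadcast_to(np.asarray(baseline_fn, dtype=float), (n,))
    with np.errstate(invalid="ignore"):
        above = np.isfinite(base) & (env >= threshold_mult * base)
    return _runs_to_spans(above, rate, merge_gap_s, min_dur_s, max_dur_s, strict_min, artifact_mask)


def refine_onset_offset(
    candidate: tuple[float, float],
    broadband_signal: np.ndarray,
    rate: float,
    baseline_value: float,
    max_shift_s: float = 1.0,
) -> tuple[float, float]:
    """Move boundaries to the bounding baseline crossings of the raw trace.

    Onset moves back to the last pre-candidate sample whose absolute value
    is at or below baseline; offset moves forward to the first such
    post-candidate sample. The search is capped at ``max_shift_s`` beyond
    each boundary, so the refined span always contains the candidate.
    """
    on, off = candidate
    i0 = int(round(on * rate))
    i1 = int(round(off * rate))
    absx = np.abs(broadband_signal)
    lo = max(0, i0 - int(round(max_shift_s * rate)))
    pre = np.flatnonzero(absx[lo:i0] <= baseline_value)
    if pre.size:
        i0 = lo + int(pre[-1])
    hi = min(len(absx), i1 + int(round(max_shift_s * rate)))
    post = np.flatnonzero(absx[i1:hi] <= baseline_value)
    if post.size:
        i1 = i1 + int(post[0]) + 1
    return (i0 / rate, i1 / rate)


def classify_laterality(
    events_left: Sequence[tuple[float, float]],
    events_right: Sequence[tuple[float, float]],
    overlap_frac: float = 0.5,
) -> list[tuple[float, float, str]]:
    """Pair per-channel candidate spans into bilateral/unilateral events.

    Two spans merge into one bilateral event (union span) when their
    intersection covers at least ``overlap_frac`` of the shorter one.
    """
    left = sorted(events_left)
    right = sorted(events_right)
    used_r = [False] * len(right)
    out: list[tuple[float, float, str]] = []
    for a0, a1 in left:
        best, best_ov = None, 0.0
        for j, (b0, b1) in enumerate(right):
            if used_r[j]:
                continue
            ov = min(a1, b1) - max(a0, b0)
            if ov > best_ov:
                best, best_ov = j, ov
        if best is not None:
            b0, b1 = right[best]
            shorter = min(a1 - a0, b1 - b0)
            if best_ov >= overlap_frac * shorter:
                used_r[best] = True
                out.append((min(a0, b0), max(a1, b1), "bilateral"))
                continue
        out.append((a0, a1, "left"))
    for j, (b0, b1) in enumerate(right):
        if not used_r[j]:
            out.append((b0, b1, "right"))
    out.sort()
    return out


def _peak_freq(
    x: np.ndarray, rate: float, band: tuple[float, float], clip: bool = True
) -> float:
    """Frequency of the largest in-band PSD bin of the event segment."""
    if len(x) < rate:
        pad = int(rate) - len(x)
        x = np.pad(x, (0, pad))
    nw = 2.0
    est = multitaper_psd(x, rate, nw=nw, n_tapers=3)
    sel = (est.freqs >= band[0]) & (est.freqs <= band[1])
    if not sel.any():
        return float(np.clip((band[0] + band[1]) / 2, *band))
    f = float(est.freqs[sel][np.argmax(est.psd[sel])])
    return float(np.clip(f, band[0], band[1])) if clip else f


def _per_second_baseline(
    env: np.ndarray,
    rate: float,
    labels: np.ndarray,
    excluded: np.ndarray,
    stat: str = "median",
) -> tuple[np.ndarray, np.ndarray]:
    """(baseline, sd) per 1-s block from preceding same-state clean blocks.

    Block values are medians (or means) of the envelope; the baseline for
    block ``t`` aggregates the nearest preceding eligible blocks up to 10,
    looking back at most 60 s. Blocks with no eligible history get NaN.
    """
    n = int(round(rate))
    n_blocks = min(len(labels), env.size // n)
    blk = env[: n_blocks * n].reshape(n_blocks, n)
    blk_med = np.median(blk, axis=1) if stat == "median" else blk.mean(axis=1)
    blk_sq = np.mean(blk**2, axis=1)
    base = np.full(n_blocks, np.nan)
    sd = np.full(n_blocks, np.nan)
    want = int(BASELINE_WINDOW_S)
    max_back = int(BASELINE_MAX_LOOKBACK_S)
    for t in range(n_blocks):
        picked = _eligible_lookback_blocks(t, labels, excluded, want, max_back)
        if not picked:
            continue
        vals = blk_med[picked]
        base[t] = np.median(vals) if stat == "median" else np.mean(vals)
        mean_sq = float(np.mean(blk_sq[picked]))
        mean_env = float(np.mean(blk.reshape(n_blocks, n)[picked].mean(axis=1)))
        sd[t] = np.sqrt(max(mean_sq - mean_env**2, 0.0))
    return base, sd


def _spindle_threshold_blocks(
    bp: np.ndarray,
    env: np.ndarray,
    rate: float,
    labels: np.ndarray,
    excluded: np.ndarray,
    sd_mult: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block spindle threshold and floor (the baseline envelope mean).

    The SD is that of the raw band-passed baseline signal (not of its
    envelope): the envelope of band noise fluctuates slowly, and an
    envelope-SD threshold admits frequent noise runs longer than 0.5 s.
    """
    n = int(round(rate))
    n_blocks = min(len(labels), env.size // n)
    blk_env_mean = env[: n_blocks * n].reshape(n_blocks, n).mean(axis=1)
    blk_sig_ms = np.mean(bp[: n_blocks * n].reshape(n_blocks, n) ** 2, axis=1)
    thresh = np.full(n_blocks, np.nan)
    floor = np.full(n_blocks, np.nan)
    want = int(BASELINE_WINDOW_S)
    max_back = int(BASELINE_MAX_LOOKBACK_S)
    for t in range(n_blocks):
        picked = _eligible_lookback_blocks(t, labels, excluded, want, max_back)
        if not picked:
            continue
        mean_env = float(np.mean(blk_env_mean[picked]))
        sd_sig = float(np.sqrt(np.mean(blk_sig_ms[picked])))
        thresh[t] = mean_env + sd_mult * sd_sig
        floor[t] = mean_env + 0.5 * sd_mult * sd_sig
    return thresh, floor


def _expand_to_samples(block_vals: np.ndarray, rate: float, n_samples: int) -> np.ndarray:
    n = int(round(rate))
    out = np.repeat(block_vals, n)
    if out.size < n_samples:
        out = np.pad(out, (0, n_samples - out.size), constant_values=np.nan)
    return out[:n_samples]


def _mult_for_state(labels: np.ndarray, rate: float, n_samples: int) -> np.ndarray:
    mult_blocks = np.where(labels == "NREM", SWD_MULT_NREM, SWD_MULT_WAKE_REM)
    return _expand_to_samples(mult_blocks, rate, n_samples)


def _discharge_candidates_one_channel(
    x: np.ndarray,
    rate: float,
    labels: np.ndarray,
    artifact_sec: np.ndarray,
    artifact_samples: np.ndarray,
    merge_gap_s: float,
) -> dict[str, list[tuple[float, float, float]]]:
    """Candidates per kind on one channel: (onset, offset, envelope ratio).

    Two passes: baselines are first computed from state/artifact
    eligibility alone, then recomputed excluding the seconds covered by
    pass-1 detections, and detection is repeated with the clean baselines.
    """
    n_samples = len(x)
    n_sec = len(labels)
    env_delta = band_envelope(x, rate, BANDS["delta_staging"])
    env_broad = band_envelope(x, rate, BANDS["total"])
    envs = {
        k: band_envelope(x, rate, _detection_band(BANDS[k.lower()]))
        for k in ("SWD", "SSWD")
    }

    def run(excluded: np.ndarray) -> dict[str, list[tuple[float, float, float]]]:
        base_delta, _ = _per_second_baseline(env_delta, rate, labels, excluded)
        base_broad, _ = _per_second_baseline(env_broad, rate, labels, excluded)
        nrem_sec = labels == "NREM"
        base_blocks = np.where(nrem_sec[: len(base_delta)], base_delta, base_broad)
        base = _expand_to_samples(base_blocks, rate, n_samples)
        mult = _mult_for_state(labels, rate, n_samples)
        found: dict[str, list[tuple[float, float, float]]] = {}
        for kind in ("SWD", "SSWD"):
            env = envs[kind]
            with np.errstate(invalid="ignore"):
                above = np.isfinite(base) & (env >= mult * base)
            spans = _runs_to_spans(above, rate, merge_gap_s, 1.0, None, True, artifact_samples)
            out = []
            for a, b in spans:
                i, j = int(a * rate), int(b * rate)
                denom = np.nanmedian(base[i:j]) * np.nanmedian(mult[i:j])
                ratio = float(np.max(env[i:j]) / denom) if denom > 0 else np.inf
                out.append((a, b, ratio))
            found[kind] = out
        return found

    pass1 = run(artifact_sec.copy())
    excl = artifact_sec.copy()
    for spans in pass1.values():
        for a, b, _ in spans:
            excl[int(a) : min(n_sec, int(np.ceil(b)))] = True
    return run(excl)


def _runs_to_spans(above, rate, merge_gap_s, min_dur_s, max_dur_s, strict_min, artifact_mask):
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    gaps = np.diff(idx)
    gap_samples = int(round(merge_gap_s * rate))
    breaks = np.flatnonzero(gaps > gap_samples)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    out = []
    for s, e in zip(starts, stops):
        dur = (e - s) / rate
        if strict_min and dur <= min_dur_s:
            continue
        if not strict_min and dur < min_dur_s:
            continue
        if max_dur_s is not None and dur > max_dur_s:
            continue
        if artifact_mask is not None and artifact_mask[s:e].any():
            continue
        out.append((s / rate, e / rate))
    return out


def _resolve_kind_overlaps(
    cands: dict[str, list[tuple[float, float, float]]],
    x: np.ndarray,
    rate: float,
):
    """Where SWD and SSWD detections overlap, keep one kind per span.

    A discharge's harmonics leak across the 6 Hz boundary, so both
    detectors usually fire on the same train. The kind is decided by the
    peak frequency of the overlapping span across the union band 3-12 Hz:
    fundamental below 6 Hz means SSWD, at or above means SWD.
    """
    swd = cands.get("SWD", [])
    sswd = cands.get("SSWD", [])
    drop_swd, drop_sswd = set(), set()
    for i, (a0, a1, _) in enumerate(swd):
        for j, (b0, b1, _) in enumerate(sswd):
            if a0 < b1 and b0 < a1:
                u0, u1 = min(a0, b0), max(a1, b1)
                seg = x[int(u0 * rate) : int(u1 * rate)]
                f = _peak_freq(seg, rate, (3.0, 12.0))
                if f >= 6.0:
                    drop_sswd.add(j)
                else:
                    drop_swd.add(i)
    return {
        "SWD": [c for i, c in enumerate(swd) if i not in drop_swd],
        "SSWD": [c for j, c in enumerate(sswd) if j not in drop_sswd],
    }


def _merge_spans(spans: list[tuple[float, float]], gap_s: float = 0.0) -> list[tuple[float, float]]:
    """Union of overlapping (or near-adjacent) spans on one channel.

    Boundary refinement can stretch neighbouring suprathreshold runs of
    one discharge until they touch; merging keeps one event per train.
    """
    out: list[tuple[float, float]] = []
    for a, b in sorted(spans):
        if out and a <= out[-1][1] + gap_s:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _dedup_cross_kind(events: list[EventInterval], record: SignalRecord) -> list[EventInterval]:
    """Final pass: one discharge kind per time span across channels.

    Per-channel kind resolution cannot see a leaked opposite-kind
    candidate on the other channel, so overlapping SWD/SSWD events can
    still coexist after laterality pairing. Where they overlap, the union
    span's 3-12 Hz peak frequency decides which survives.
    """
    rate = record.rate
    x = record.channels[record.eeg_names[0]]
    swd = [e for e in events if e.kind == "SWD"]
    sswd = [e for e in events if e.kind == "SSWD"]
    other = [e for e in events if e.kind not in ("SWD", "SSWD")]
    drop_swd: set[int] = set()
    drop_sswd: set[int] = set()
    for i, e in enumerate(swd):
        for j, f in enumerate(sswd):
            if i in drop_swd or j in drop_sswd or not e.overlaps(f):
                continue
            u0, u1 = min(e.onset_s, f.onset_s), max(e.offset_s, f.offset_s)
            seg = x[int(u0 * rate) : int(u1 * rate)]
            if _peak_freq(seg, rate, (3.0, 12.0)) >= 6.0:
                drop_sswd.add(j)
            else:
                drop_swd.add(i)
    kept = (
        [e for i, e in enumerate(swd) if i not in drop_swd]
        + [f for j, f in enumerate(sswd) if j not in drop_sswd]
        + other
    )
    kept.sort(key=lambda e: (e.onset_s, e.kind))
    return kept


def detect_swd(
    record: SignalRecord,
    hyp: Hypnogram,
    merge_gap_s: float = MERGE_GAP_S,
    overlap_frac: float = 0.5,
) -> list[EventInterval]:
    """Detect SWDs (6-12 Hz) and SSWDs (3-6 Hz) on both EEG channels.

    Thresholds are 2x the preceding broadband baseline in wake/REM and
    1.5x the preceding delta baseline in NREM, per candidate-onset state.
    Boundaries are refined to broadband baseline crossings; per-channel
    detections are merged into bilateral events at >= ``overlap_frac``
    overlap of the shorter; each event takes the state at its onset.
    """
    if hyp.n_epochs == 0:
        raise InputError("record is not staged")
    rate = record.rate
    n_sec = int(record.duration_s)
    labels = _second_labels(hyp, n_sec)
    artifact_sec = np.zeros(n_sec, dtype=bool)
    for a, b in record.artifact_mask:
        artifact_sec[int(a) : min(n_sec, int(np.ceil(b)))] = True
    art_samples = record.artifact_sample_mask()
    names = record.eeg_names
    per_channel: dict[str, dict[str, list[tuple[float, float, float]]]] = {}
    broad = {}
    base_broad_blocks = {}
    for name in names:
        x = record.channels[name]
        cands = _discharge_candidates_one_channel(
            x, rate, labels, artifact_sec, art_samples, merge_gap_s
        )
        per_channel[name] = _resolve_kind_overlaps(cands, x, rate)
        broad[name] = bandpass_array(x, rate, FilterSpec(*BANDS["total"]))
        env_b = np.abs(hilbert(broad[name]))
        excl = artifact_sec.copy()
        for spans in per_channel[name].values():
            for a, b, _ in spans:
                excl[int(a) : min(n_sec, int(np.ceil(b)))] = True
        base_broad_blocks[name], _ = _per_second_baseline(env_b, rate, labels, excl)

    events: list[EventInterval] = []
    for kind in ("SWD", "SSWD"):
        refined = {}
        for name in names:
            spans = []
            for a, b, _ in per_channel[name][kind]:
                blk = min(int(a), len(base_broad_blocks[name]) - 1)
                bval = base_broad_blocks[name][blk]
                if not np.isfinite(bval):
                    bval = float(np.median(np.abs(broad[name])))
                spans.append(refine_onset_offset((a, b), broad[name], rate, bval))
            refined[name] = _merge_spans(spans, gap_s=merge_gap_s)
        lat = classify_laterality(refined[names[0]], refined[names[1]], overlap_frac)
        band = BANDS[kind.lower()]
        for a, b, side in lat:
            if b - a <= 1.0:  # refined span must still exceed the train minimum
                continue
            src = record.channels[names[0] if side != "right" else names[1]]
            seg = src[int(a * rate) : int(b * rate)]
            # the detection filter is padded beyond the nominal band; the
            # event must still peak inside the band itself
            pf = _peak_freq(seg, rate, _detection_band(band), clip=False)
            if not (band[0] <= pf <= band[1]):
                continue
            onset_state = labels[min(int(a), n_sec - 1)]
            events.append(
                EventInterval(
                    onset_s=a,
                    offset_s=b,
                    kind=kind,
                    band_lo_hz=band[0],
                    band_hi_hz=band[1],
                    peak_freq_hz=_peak_freq(seg, rate, band),
                    laterality=side,
                    state=str(onset_state),
                    channel_roles=("eeg_left", "eeg_right") if side == "bilateral"
                    else (("eeg_left",) if side == "left" else ("eeg_right",)),
                )
            )
    return _dedup_cross_kind(events, record)


def detect_spindles(
    record: SignalRecord,
    hyp: Hypnogram,
    swd_events: Sequence[EventInterval] = (),
    sd_mult: float = SPINDLE_SD_MULT,
) -> list[EventInterval]:
    """Detect sleep spindles (10-15 Hz, 0.5-5 s) on both EEG channels.

    The threshold is the preceding 10 s baseline envelope mean plus
    ``sd_mult`` SDs of the band-passed baseline signal (same state,
    event- and artifact-free). Detection is restricted to NREM epochs
    (spindles are an NREM rhythm); spans overlapping an SWD/SSWD are
    discarded; per-channel spans merge bilaterally like discharges.
    """
    rate = record.rate
    n_sec = int(record.duration_s)
    labels = _second_labels(hyp, n_sec)
    artifact_sec = np.zeros(n_sec, dtype=bool)
    for a, b in record.artifact_mask:
        artifact_sec[int(a) : min(n_sec, int(np.ceil(b)))] = True
    excl = artifact_sec.copy()
    for e in swd_events:
        excl[int(e.onset_s) : min(n_sec, int(np.ceil(e.offset_s)))] = True
    art_samples = record.artifact_sample_mask()
    names = record.eeg_names
    band = BANDS["spindle"]
    nrem_samples = _expand_to_samples(
        (labels == "NREM").astype(float), rate, record.n_samples
    ) > 0.5
    per_channel = {}
    for name in names:
        bp = bandpass_array(record.channels[name], rate, FilterSpec(*band))
        env = np.abs(hilbert(bp))
        # 0.2-s moving-average smoothing of the envelope: raw band-noise
        # envelope dips fragment a spindle into sub-0.5 s runs
        k = max(1, int(round(0.2 * rate)))
        env_s = np.convolve(env, np.ones(k) / k, mode="same")

        def run(excluded: np.ndarray) -> list[tuple[float, float]]:
            thresh_blocks, floor_blocks = _spindle_threshold_blocks(
                bp, env, rate, labels, excluded, sd_mult
            )
            thresh = _expand_to_samples(thresh_blocks, rate, len(env))
            floor = _expand_to_samples(floor_blocks, rate, len(env))
            with np.errstate(invalid="ignore"):
                above = np.isfinite(thresh) & (env_s >= thresh) & nrem_samples
            cores = _runs_to_spans(above, rate, MERGE_GAP_S, 0.3, 5.0, False, art_samples)
            # dual threshold: a spindle waxes and wanes, so only its crest
            # crosses mean + k SD; boundaries extend outward to where the
            # envelope falls to mean + k/2 SD (capped at 1 s). The 0.5-5 s
            # duration gate applies to the extended event.
            cap = int(round(rate))
            spans = []
            with np.errstate(invalid="ignore"):
                low = (env_s >= floor) & nrem_samples & ~art_samples
            for a, b in cores:
                i, j = int(round(a * rate)), int(round(b * rate))
                lo = max(0, i - cap)
                below = np.flatnonzero(~low[lo:i])
                i = lo + int(below[-1]) + 1 if below.size else lo
                hi = min(len(low), j + cap)
                below = np.flatnonzero(~low[j:hi])
                j = j + int(below[0]) if below.size else hi
                spans.append((i / rate, j / rate))
            spans = _merge_spans(spans, gap_s=MERGE_GAP_S)
            return [(a, b) for a, b in spans if 0.5 <= b - a <= 5.0]

        # two passes: a spindle shortly after another would inflate the
        # second one's baseline, so pass-1 detections are excluded from
        # the lookback and detection is repeated
        pass1 = run(excl)
        excl2 = excl.copy()
        for a, b in pass1:
            excl2[int(a) : min(n_sec, int(np.ceil(b)))] = True
        per_channel[name] = run(excl2)
    lat = classify_laterality(per_channel[names[0]], per_channel[names[1]])
    out: list[EventInterval] = []
    for a, b, side in lat:
        if not (0.5 <= b - a <= 5.0):
            continue
        if any(a < e.offset_s and e.onset_s < b for e in swd_events):
            continue
        src = record.channels[names[0] if side != "right" else names[1]]
        seg = src[int(a * rate) : int(b * rate)]
        out.append(
            EventInterval(
                onset_s=a,
                offset_s=b,
                kind="spindle",
                band_lo_hz=band[0],
                band_hi_hz=band[1],
                peak_freq_hz=_peak_freq(seg, rate, band),
                laterality=side,
                state=str(labels[min(int(a), n_sec - 1)]),
                channel_roles=("eeg_left", "eeg_right") if side == "bilateral"
                else (("eeg_left",) if side == "left" else ("eeg_right",)),
            )
        )
    out.sort(key=lambda e: e.onset_s)
    return out


def assign_state(events: Sequence[EventInterval], hyp: Hypnogram) -> list[EventInterval]:
    """Set each event's state to the hypnogram sub-label at its onset."""
    out = []
    for e in events:
        if e.onset_s >= len(hyp.sub_labels):
            raise InputError(f"event onset {e.onset_s:.3f} s outside hypnogram span")
        state = hyp.state_at(e.onset_s)
        out.append(
            EventInterval(
                onset_s=e.onset_s,
                offset_s=e.offset_s,
                kind=e.kind,
                band_lo_hz=e.band_lo_hz,
                band_hi_hz=e.band_hi_hz,
                peak_freq_hz=e.peak_freq_hz,
                laterality=e.laterality,
                state=state,
                channel_roles=e.channel_roles,
            )
        )
    return out
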