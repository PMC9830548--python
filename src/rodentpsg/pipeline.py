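"""End-to-end quantification of one record: stage, detect, summarize."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EventInterval, Hypnogram, SignalRecord
from .events import detect_spindles, detect_swd
from .preprocess import ANALYSIS_RATE_HZ, mask_artifacts, resample_to
from .spectral import nrem_delta_power
from .staging import (
    StateMetrics,
    calibrate_thresholds,
    compute_epoch_features,
    score_epochs,
    summarize_states,
)
from .stats_summary import AnimalMetrics, incidence_metrics

__all__ = ["PipelineResult", "analyze_record"]


@dataclass
class PipelineResult:
    record: SignalRecord  # at the analysis rate, artifact-masked
    hypnogram: Hypnogram
    events: list[EventInterval]
    state_metrics: StateMetrics
    animal_metrics: AnimalMetrics


def analyze_record(
    record: SignalRecord,
    animal_id: str = "animal",
    genotype: str = "het",
    sex: str = "M",
    phase: str = "baseline",
    mask_emg_artifacts: bool = True,
    delta_power_total_s: float | None = None,
) -> PipelineResult:
    """Run the full chain on one record.

    Resamples to 200 Hz, masks EMG-detected movement artifacts, stages
    10-s epochs, detects SWD/SSWD then spindles, and computes per-state
    incidence metrics. ``delta_power_total_s`` (seconds of NREM windows)
    enables the NREM delta-power statistic; it is skipped when None or
    when the record has too little NREM.
    """
    rec = resample_to(record, ANALYSIS_RATE_HZ) if record.rate != ANALYSIS_RATE_HZ else record.copy()
    if mask_emg_artifacts:
        rec = mask_artifacts(rec)
    feats = compute_epoch_features(rec)
    th = calibrate_thresholds(feats)
    hyp = score_epochs(feats, th)
    discharges = detect_swd(rec, hyp)
    spindles = detect_spindles(rec, hyp, swd_events=discharges)
    events = sorted(discharges + spindles, key=lambda e: (e.onset_s, e.kind))
    sm = summarize_states(hyp)
    am = incidence_metrics(
        events, sm, hyp, animal_id=animal_id, genotype=genotype, sex=sex, phase=phase
    )
    if delta_power_total_s is not None:
        am.nrem_delta_power_mv2_hz = nrem_delta_power(
            rec, hyp, total_s=delta_power_total_s
        )
    return PipelineResult(
        record=rec,
        hypnogram=hyp,
        events=events,
        state_metrics=sm,
        animal_metrics=am,
    )
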