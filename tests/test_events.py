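import numpy as np
import pytest

from rodentpsg.core import Hypnogram, SignalRecord
from rodentpsg.events import (
    band_envelope,
    classify_laterality,
    detect_band_events,
    detect_spindles,
    detect_swd,
    estimate_baseline,
    refine_onset_offset,
)

RATE = 200.0


def hyp_all(state, n_sec):
    labels = [state] * (n_sec // 10)
    return Hypnogram(labels=labels, sub_labels=np.asarray([state] * n_sec, "U8"))


def wake_record(n_sec=120, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    n = int(n_sec * RATE)
    mk = lambda: noise * rng.standard_normal(n)
    return SignalRecord(
        channels={"L": mk(), "R": mk(), "M": 0.1 * rng.standard_normal(n)},
        rate=RATE,
        roles={"L": "eeg_left", "R": "eeg_right", "M": "emg"},
    )


def add_burst(rec, names, f_hz, t0, dur, amp):
    t = np.arange(int(dur * RATE)) / RATE
    w = amp * np.sin(2 * np.pi * f_hz * t)
    i = int(t0 * RATE)
    for name in names:
        rec.channels[name][i : i + len(w)] += w


class TestEstimateBaseline:
    def test_sine_amplitude_recovered(self):
        t = np.arange(int(60 * RATE)) / RATE
        x = 0.4 * np.sin(2 * np.pi * 5.0 * t)
        est = estimate_baseline(x, RATE, 30.0, hyp_all("wake", 60), kind="SWD")
        assert est.value == pytest.approx(0.4, rel=0.05)
        assert est.band == (0.5, 30.0)

    def test_nrem_uses_delta_band(self):
        t = np.arange(int(60 * RATE)) / RATE
        x = 0.2 * np.sin(2 * np.pi * 2.0 * t) + 0.2 * np.sin(2 * np.pi * 20.0 * t)
        est = estimate_baseline(x, RATE, 30.0, hyp_all("NREM", 60), kind="SWD")
        # delta-band envelope sees only the 2 Hz component
        assert est.value == pytest.approx(0.2, rel=0.1)
        assert est.band == (0.5, 4.0)

    def test_no_eligible_window_returns_none(self):
        x = np.zeros(int(30 * RATE))
        labels = ["wake"] * 10 + ["NREM"] * 20
        hyp = Hypnogram(
            labels=["wake", "NREM", "NREM"], sub_labels=np.asarray(labels, "U8")
        )
        excl = np.ones(30, dtype=bool)  # everything excluded
        assert estimate_baseline(x, RATE, 25.0, hyp, "SWD", excluded_seconds=excl) is None


def brute_force_spans(env, base, mult, rate, merge_gap_s, min_dur_s, strict_min):
    """Independent re-implementation of the span logic with explicit loops."""
    above = [bool(np.isfinite(b) and e >= mult * b) for e, b in zip(env, base)]
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    gap = int(round(merge_gap_s * rate))
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    out = []
    for s, e in merged:
        dur = (e - s) / rate
        keep = dur > min_dur_s if strict_min else dur >= min_dur_s
        if keep:
            out.append((s / rate, e / rate))
    return out


class TestDetectBandEventsOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_records(self, seed):
        rng = np.random.default_rng(seed)
        n = int(60 * RATE)
        x = 0.05 * rng.standard_normal(n)
        # a few random in-band bursts
        for _ in range(rng.integers(1, 4)):
            t0 = float(rng.uniform(5, 50))
            dur = float(rng.uniform(0.5, 3.0))
            f = float(rng.uniform(6.5, 11.5))
            t = np.arange(int(dur * RATE)) / RATE
            i = int(t0 * RATE)
            x[i : i + len(t)] += 0.3 * np.sin(2 * np.pi * f * t)
        base = float(rng.uniform(0.02, 0.08))
        mult = 2.0
        got = detect_band_events(
            x, RATE, (6.0, 12.0), mult, base, min_dur_s=0.5, merge_gap_s=0.3
        )
        env = band_envelope(x, RATE, (6.0, 12.0))
        want = brute_force_spans(
            env, np.full(n, base), mult, RATE, 0.3, 0.5, strict_min=True
        )
        assert got == want


class TestRefineOnsetOffset:
    def test_refined_span_contains_candidate_within_cap(self):
        rng = np.random.default_rng(4)
        x = 0.02 * rng.standard_normal(int(30 * RATE))
        add = np.sin(2 * np.pi * 8 * np.arange(int(2 * RATE)) / RATE)
        i = int(10 * RATE)
        x[i : i + len(add)] += 0.5 * add
        on, off = refine_onset_offset((10.2, 11.8), x, RATE, baseline_value=0.06)
        assert on <= 10.2 and off >= 11.8
        assert on >= 9.2 and off <= 12.8  # 1-s cap
        # boundaries sit at sub-baseline samples
        assert abs(x[int(round(on * RATE))]) <= 0.06


class TestLaterality:
    def test_60_percent_overlap_is_bilateral_union(self):
        out = classify_laterality([(10.0, 12.0)], [(11.0, 12.5)])
        # intersection 1.0 s, shorter span 1.5 s -> 67% >= 50%
        assert out == [(10.0, 12.5, "bilateral")]

    def test_40_percent_overlap_stays_unilateral(self):
        out = classify_laterality([(10.0, 12.0)], [(11.5, 14.0)])
        # intersection 0.5 s, shorter 2.0 s -> 25% < 50%
        assert out == [(10.0, 12.0, "left"), (11.5, 14.0, "right")]

    def test_single_channel_events(self):
        assert classify_laterality([], [(1.0, 2.5)]) == [(1.0, 2.5, "right")]


class TestDetectSwd:
    def test_bilateral_wake_swd_recovered(self):
        rec = wake_record(seed=5)
        add_burst(rec, ("L", "R"), 9.0, 60.0, 2.0, amp=0.25)  # 5x the noise floor
        events = detect_swd(rec, hyp_all("wake", 120))
        swds = [e for e in events if e.kind == "SWD"]
        assert len(swds) == 1
        e = swds[0]
        assert e.laterality == "bilateral"
        assert abs(e.onset_s - 60.0) <= 0.5
        assert e.state == "wake"
        assert 6.0 <= e.peak_freq_hz <= 12.0

    def test_unilateral_swd_lateralized(self):
        rec = wake_record(seed=6)
        add_burst(rec, ("R",), 8.0, 60.0, 2.0, amp=0.25)
        events = detect_swd(rec, hyp_all("wake", 120))
        swds = [e for e in events if e.kind == "SWD"]
        assert len(swds) == 1 and swds[0].laterality == "right"

    def test_sub_second_burst_rejected(self):
        rec = wake_record(seed=7)
        add_burst(rec, ("L", "R"), 9.0, 60.0, 0.8, amp=0.25)  # <= 1 s rule
        events = detect_swd(rec, hyp_all("wake", 120))
        assert [e for e in events if e.kind == "SWD"] == []

    def test_artifact_overlap_discarded(self):
        rec = wake_record(seed=8)
        add_burst(rec, ("L", "R"), 9.0, 60.0, 2.0, amp=0.25)
        rec.artifact_mask = [(60.5, 61.0)]
        events = detect_swd(rec, hyp_all("wake", 120))
        assert [e for e in events if e.kind == "SWD"] == []

    def test_sswd_band_assignment(self):
        rec = wake_record(seed=9)
        add_burst(rec, ("L", "R"), 4.5, 60.0, 2.0, amp=0.3)
        events = detect_swd(rec, hyp_all("wake", 120))
        kinds = {e.kind for e in events}
        assert "SSWD" in kinds and "SWD" not in kinds


class TestSpindleGates:
    def nrem_record(self, seed=10, n_sec=120):
        rng = np.random.default_rng(seed)
        n = int(n_sec * RATE)
        mk = lambda: 0.04 * rng.standard_normal(n) + 0.1 * np.sin(
            2 * np.pi * 2.0 * np.arange(n) / RATE
        )
        return SignalRecord(
            channels={"L": mk(), "R": mk(), "M": 0.01 * rng.standard_normal(n)},
            rate=RATE,
            roles={"L": "eeg_left", "R": "eeg_right", "M": "emg"},
        )

    def test_valid_spindle_detected_with_gated_duration(self):
        rec = self.nrem_record()
        add_burst(rec, ("L", "R"), 12.0, 60.0, 1.5, amp=0.2)
        out = detect_spindles(rec, hyp_all("NREM", 120))
        assert len(out) == 1
        assert 0.5 <= out[0].duration_s <= 5.0
        assert out[0].kind == "spindle" and out[0].state == "NREM"

    def test_too_short_burst_rejected(self):
        rec = self.nrem_record(seed=11)
        add_burst(rec, ("L", "R"), 12.0, 60.0, 0.2, amp=0.2)
        assert detect_spindles(rec, hyp_all("NREM", 120)) == []

    def test_too_long_burst_rejected(self):
        rec = self.nrem_record(seed=12)
        add_burst(rec, ("L", "R"), 12.0, 60.0, 8.0, amp=0.2)
        assert detect_spindles(rec, hyp_all("NREM", 120)) == []

    def test_span_claimed_by_swd_discarded(self):
        rec = self.nrem_record(seed=13)
        add_burst(rec, ("L", "R"), 12.0, 60.0, 1.5, amp=0.2)
        from rodentpsg.core import EventInterval

        swd = EventInterval(59.5, 62.0, "SWD", 6.0, 12.0, 11.0, "bilateral", "NREM")
        out = detect_spindles(rec, hyp_all("NREM", 120), swd_events=[swd])
        assert not any(e.onset_s < 62.0 and 59.5 < e.offset_s for e in out)

    def test_outside_nrem_not_detected(self):
        rec = self.nrem_record(seed=14)
        add_burst(rec, ("L", "R"), 12.0, 60.0, 1.5, amp=0.2)
        assert detect_spindles(rec, hyp_all("wake", 120)) == []
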