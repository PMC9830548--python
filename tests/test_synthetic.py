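import dataclasses

import numpy as np
import pytest

from rodentpsg.core import ParameterError
from rodentpsg.synthetic import (
    GeneratorSpec,
    StateParams,
    _default_states,
    generate_record,
    make_cohort,
    realize_animal,
    sample_state_sequence,
    swo_protocol_track,
)

SHORT = dict(duration_s=600.0, rate=200.0)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a_rec, a_truth = generate_record(GeneratorSpec(seed=42, **SHORT))
        b_rec, b_truth = generate_record(GeneratorSpec(seed=42, **SHORT))
        for name in a_rec.channels:
            assert a_rec.channels[name].tobytes() == b_rec.channels[name].tobytes()
        assert a_truth.state_seconds.tobytes() == b_truth.state_seconds.tobytes()
        assert a_truth.events == b_truth.events
        assert a_truth.artifact_intervals == b_truth.artifact_intervals

    def test_different_seeds_differ(self):
        a, _ = generate_record(GeneratorSpec(seed=1, **SHORT))
        b, _ = generate_record(GeneratorSpec(seed=2, **SHORT))
        assert not np.array_equal(a.channels["EEG L"], b.channels["EEG L"])


class TestStateSequence:
    def test_every_second_labeled(self):
        truth = sample_state_sequence(GeneratorSpec(seed=3, duration_s=3600.0))
        assert truth.state_seconds.shape == (3600,)
        assert set(np.unique(truth.state_seconds)) <= {"wake", "NREM", "REM"}

    def test_all_states_visited_in_an_hour(self):
        truth = sample_state_sequence(GeneratorSpec(seed=4, duration_s=3600.0))
        assert set(np.unique(truth.state_seconds)) == {"wake", "NREM", "REM"}

    def test_short_dwell_rejected(self):
        states = _default_states()
        states["REM"] = StateParams(dwell_mean_s=5.0)
        with pytest.raises(ParameterError):
            GeneratorSpec(state_params=states)

    def test_epoch_labels_majority(self):
        truth = sample_state_sequence(GeneratorSpec(seed=5, duration_s=600.0))
        labels = truth.epoch_labels()
        assert len(labels) == 60
        seg = truth.state_seconds[:10]
        vals, counts = np.unique(seg, return_counts=True)
        assert labels[0] == vals[np.argmax(counts)]


class TestGeneratedRecord:
    def test_channels_and_rate(self):
        rec, _ = generate_record(GeneratorSpec(seed=6, **SHORT))
        assert set(rec.channels) == {"EEG L", "EEG R", "EMG"}
        assert rec.rate == 200.0
        assert rec.n_samples == 600 * 200

    def test_truth_events_valid_and_in_state(self):
        rec, truth = generate_record(GeneratorSpec(seed=7, duration_s=1800.0, rate=200.0))
        assert truth.events, "expected injected events"
        for e in truth.events:
            assert e.onset_s >= 0 and e.offset_s <= 1800.0
            # event lies fully inside a run of its labeled state
            secs = truth.state_seconds[int(e.onset_s) : int(np.ceil(e.offset_s))]
            assert all(s == e.state for s in secs)
            if e.kind in ("SWD", "SSWD"):
                assert e.duration_s > 1.0
            else:
                assert 0.5 <= e.duration_s <= 5.0

    def test_truth_events_sorted_and_non_overlapping(self):
        _, truth = generate_record(GeneratorSpec(seed=8, duration_s=1800.0, rate=200.0))
        ons = [e.onset_s for e in truth.events]
        assert ons == sorted(ons)
        for a, b in zip(truth.events, truth.events[1:]):
            assert b.onset_s >= a.offset_s

    def test_nrem_has_more_delta_than_wake(self):
        rec, truth = generate_record(GeneratorSpec(seed=9, duration_s=1800.0, rate=200.0))
        from rodentpsg.events import band_envelope

        env = band_envelope(rec.channels["EEG L"], 200.0, (0.5, 4.0))
        sec = env[: 1800 * 200].reshape(1800, 200).mean(axis=1)
        nrem = sec[truth.state_seconds == "NREM"].mean()
        wake = sec[truth.state_seconds == "wake"].mean()
        assert nrem > 1.5 * wake

    def test_artifacts_only_in_wake(self):
        _, truth = generate_record(GeneratorSpec(seed=10, duration_s=1800.0, rate=200.0))
        for a, b in truth.artifact_intervals:
            secs = truth.state_seconds[int(a) : int(np.ceil(b))]
            assert all(s == "wake" for s in secs)


class TestCohort:
    def design(self):
        return [
            {"genotype": "het", "sex": "M", "n": 3, "phases": ["pre", "post"]},
            {"genotype": "het", "sex": "F", "n": 2, "phases": ["baseline"]},
        ]

    def test_size_ids_and_seed_bounds(self):
        cohort = make_cohort(self.design(), GeneratorSpec(**SHORT), seed=11)
        assert len(cohort) == 3 * 2 + 2
        assert len({(a.animal_id, a.phase) for a in cohort}) == len(cohort)
        for a in cohort:
            assert 0 <= a.spec.seed < 2**31

    def test_phase_effect_scales_post_rates(self):
        base = GeneratorSpec(phase_effect={"swd_rate": 2.0, "nrem_dwell": 1.0}, **SHORT)
        cohort = make_cohort(self.design(), base, seed=12)
        by = {(a.animal_id, a.phase): a for a in cohort}
        pre = by[("het_M_001", "pre")].spec
        post = by[("het_M_001", "post")].spec
        for state in ("wake", "NREM", "REM"):
            r_pre = pre.event_params["SWD"].rates_per_hr[state]
            r_post = post.event_params["SWD"].rates_per_hr[state]
            if r_pre > 0:
                assert r_post == pytest.approx(2.0 * r_pre)

    def test_random_effect_shared_across_phases(self):
        cohort = make_cohort(self.design(), GeneratorSpec(**SHORT), seed=13)
        by = {(a.animal_id, a.phase): a for a in cohort}
        pre = by[("het_M_002", "pre")].spec
        post = by[("het_M_002", "post")].spec
        # default phase_effect is 1.0, so pre and post rates must be equal
        assert pre.event_params["SWD"].rates_per_hr == post.event_params["SWD"].rates_per_hr

    def test_sex_effect_on_female_nrem_delta(self):
        base = GeneratorSpec(sex_effect=2.0, **SHORT)
        cohort = make_cohort(self.design(), base, seed=14)
        f = next(a for a in cohort if a.sex == "F")
        m = next(a for a in cohort if a.sex == "M")
        assert f.spec.state_params["NREM"].delta_amp_mv == pytest.approx(
            2.0 * m.spec.state_params["NREM"].delta_amp_mv
        )

    def test_realize_animal_deterministic(self):
        cohort = make_cohort(self.design(), GeneratorSpec(**SHORT), seed=15)
        a1, _ = realize_animal(cohort[0])
        a2, _ = realize_animal(cohort[0])
        assert a1.channels["EEG L"].tobytes() == a2.channels["EEG L"].tobytes()


class TestSwoProtocol:
    def test_default_counts(self):
        p = swo_protocol_track()
        assert p.n_cycles == 300
        assert len(p.pulse_times) == 300

    def test_pulses_at_up_state_start(self):
        p = swo_protocol_track()
        for (a, b), t in zip(p.laser_intervals, p.pulse_times):
            assert t == pytest.approx(b)
            assert b - a == pytest.approx(1.8)

    def test_inconsistent_timing_rejected(self):
        with pytest.raises(ParameterError):
            swo_protocol_track(period_s=2.0, down_s=1.8, up_s=0.3)
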