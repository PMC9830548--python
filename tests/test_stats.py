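import numpy as np
import pytest
from scipy import stats as sps

from rodentpsg.core import EventInterval, Hypnogram, InputError
from rodentpsg.staging import StateMetrics
from rodentpsg.stats_summary import (
    AnimalMetrics,
    anova_oneway,
    cohort_report,
    compare_groups,
    holm_sidak,
    incidence_metrics,
    spindle_density,
)


def nrem_hyp(n_epochs):
    labels = ["NREM"] * n_epochs
    return Hypnogram(labels=labels, sub_labels=np.repeat(np.asarray(labels, "U8"), 10))


def swd(onset, dur):
    return EventInterval(onset, onset + dur, "SWD", 6.0, 12.0, 8.0, "bilateral", "NREM")


class TestIncidenceExactness:
    def test_hand_computed_example(self):
        # 12 events, 30 s total, 0.1 h (360 s) of NREM
        events = [swd(10.0 * k, 2.5) for k in range(12)]
        sm = StateMetrics(
            duration_s={"wake": 0.0, "NREM": 360.0, "REM": 0.0},
            bout_count={"wake": 0, "NREM": 1, "REM": 0},
        )
        m = incidence_metrics(events, sm, nrem_hyp(36))
        assert m.swd_count["NREM"] == 12
        assert m.swd_per_hr["NREM"] == 120.0  # 12 / 0.1 h, exact
        assert m.swd_dur_s_per_hr["NREM"] == 300.0  # 30 s / 0.1 h, exact
        assert m.swd_pct_of_state["NREM"] == 30.0 / 360.0 * 100.0  # 8.33...%
        assert m.duration_h["NREM"] == 0.1

    def test_swd_and_sswd_pooled(self):
        ev = [
            swd(10.0, 2.0),
            EventInterval(50.0, 52.0, "SSWD", 3.0, 6.0, 4.0, "left", "NREM"),
            EventInterval(80.0, 81.0, "spindle", 10.0, 15.0, 12.0, "left", "NREM"),
        ]
        sm = StateMetrics(duration_s={"wake": 0.0, "NREM": 360.0, "REM": 0.0}, bout_count={})
        m = incidence_metrics(ev, sm, nrem_hyp(36))
        assert m.swd_count["NREM"] == 2  # spindle not pooled

    def test_events_in_zero_duration_state_rejected(self):
        sm = StateMetrics(duration_s={"wake": 0.0, "NREM": 0.0, "REM": 0.0}, bout_count={})
        with pytest.raises(InputError):
            incidence_metrics([swd(10.0, 2.0)], sm, nrem_hyp(36))

    def test_spindle_density(self):
        ev = [EventInterval(5.0, 6.0, "spindle", 10.0, 15.0, 12.0, "left", "NREM")] * 3
        assert spindle_density(ev, nrem_hyp(10)) == 3 / 100.0

    def test_spindle_density_no_nrem_rejected(self):
        labels = ["wake"] * 5
        hyp = Hypnogram(labels=labels, sub_labels=np.repeat(np.asarray(labels, "U8"), 10))
        with pytest.raises(InputError):
            spindle_density([], hyp)


class TestTTest:
    def test_explicit_formula_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        comp = compare_groups(a, b)
        # pooled two-sample t by hand
        m1, m2 = np.mean(a), np.mean(b)
        s1, s2 = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = ((3 - 1) * s1 + (3 - 1) * s2) / (3 + 3 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * sps.t.sf(abs(t), 4)
        assert comp.statistic == pytest.approx(t, abs=1e-10)
        assert comp.p_value == pytest.approx(p, abs=1e-10)
        assert comp.significant
        assert comp.means == (2.0, 5.0)
        assert comp.sems[0] == pytest.approx(np.std(a, ddof=1) / np.sqrt(3))

    def test_paired_matches_scipy(self):
        a, b = [3.1, 4.2, 5.0, 6.3], [2.9, 3.8, 4.1, 5.0]
        comp = compare_groups(a, b, paired=True)
        t, p = sps.ttest_rel(a, b)
        assert comp.statistic == pytest.approx(t, abs=1e-12)
        assert comp.p_value == pytest.approx(p, abs=1e-12)

    def test_paired_identical_degenerate(self):
        comp = compare_groups([1.0, 2.0], [1.0, 2.0], paired=True)
        assert comp.degenerate and comp.p_value == 1.0 and comp.statistic == 0.0

    def test_welch(self):
        a, b = [1.0, 2.0, 3.0, 9.0], [4.0, 5.0, 6.0]
        comp = compare_groups(a, b, welch=True)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert comp.statistic == pytest.approx(t, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            compare_groups([1.0], [2.0, 3.0])

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


class TestAnova:
    def test_ss_decomposition_oracle(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(i, 1.0, 7) for i, k in enumerate("abc")}
        comp = anova_oneway(groups)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups.values())
        ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups.values())
        df_b, df_w = 2, len(allv) - 3
        f = (ss_between / df_b) / (ss_within / df_w)
        p = sps.f.sf(f, df_b, df_w)
        assert comp.statistic == pytest.approx(f, abs=1e-10)
        assert comp.p_value == pytest.approx(p, abs=1e-10)

    def test_identical_constant_groups_degenerate(self):
        comp = anova_oneway({"a": [2.0, 2.0], "b": [2.0, 2.0]}, pairwise=False)
        assert comp.degenerate and comp.p_value == 1.0

    def test_pairwise_holm_sidak_table(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(3, 1, 10), "c": rng.normal(3.1, 1, 10)}
        comp = anova_oneway(groups)
        pw = comp.pairwise
        assert set(pw.columns) >= {"a", "b", "t", "p_raw", "p_adj", "significant"}
        assert (pw["p_adj"] >= pw["p_raw"] - 1e-15).all()

    def test_too_few_groups_rejected(self):
        with pytest.raises(InputError):
            anova_oneway({"a": [1.0, 2.0]})


class TestHolmSidak:
    def test_matches_closed_form_two_tests(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 2, abs=1e-12)
        assert adj[1] == pytest.approx(0.04, abs=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        raw = [0.001, 0.02, 0.04, 0.3, 0.7]
        adj = holm_sidak(raw)
        assert (adj >= np.asarray(raw) - 1e-15).all()
        assert (np.diff(adj[np.argsort(raw)]) >= -1e-15).all()

    def test_empty(self):
        assert holm_sidak([]).size == 0


def animal(aid, genotype="het", sex="M", phase="baseline", nrem_rate=10.0, delta=1.0):
    m = AnimalMetrics(animal_id=aid, genotype=genotype, sex=sex, phase=phase)
    m.swd_per_hr = {"wake": nrem_rate / 3, "NREM": nrem_rate, "REM": nrem_rate / 4}
    m.nrem_delta_power_mv2_hz = delta
    return m


class TestCohortReport:
    def test_paired_pre_post(self):
        rng = np.random.default_rng(2)
        animals = []
        for i in range(6):
            base = 10 + rng.normal(0, 1)
            animals.append(animal(f"a{i}", phase="pre", nrem_rate=base))
            animals.append(animal(f"a{i}", phase="post", nrem_rate=base * 2))
        res = cohort_report(
            animals,
            [{"name": "post_vs_pre", "metric": "swd_per_hr:NREM", "kind": "paired"}],
        )
        comp = res.comparisons["post_vs_pre"]
        assert comp.test == "paired_t"
        assert comp.means[0] > comp.means[1]  # post > pre
        assert comp.significant
        assert len(res.table) == 2

    def test_state_anova_split(self):
        rng = np.random.default_rng(3)
        animals = [animal(f"a{i}", nrem_rate=10 + rng.normal(0, 0.5)) for i in range(6)]
        res = cohort_report(
            animals,
            [{"name": "by_state", "metric": "swd_per_hr", "kind": "anova", "split": "state"}],
        )
        comp = res.comparisons["by_state"]
        assert comp.test == "anova_oneway"
        assert comp.significant

    def test_sex_split_with_filter(self):
        rng = np.random.default_rng(4)
        animals = [
            animal(f"m{i}", sex="M", delta=1 + rng.normal(0, 0.05)) for i in range(5)
        ] + [animal(f"f{i}", sex="F", delta=2 + rng.normal(0, 0.05)) for i in range(5)]
        res = cohort_report(
            animals,
            [
                {
                    "name": "f_vs_m",
                    "metric": "nrem_delta_power_mv2_hz",
                    "kind": "unpaired",
                    "split": "sex",
                    "filter": {"phase": "baseline"},
                }
            ],
        )
        comp = res.comparisons["f_vs_m"]
        assert comp.group_labels == ("F", "M")
        assert comp.means[0] > comp.means[1]
        assert comp.significant

    def test_unpairable_animals_rejected(self):
        animals = [animal("a1", phase="pre"), animal("a2", phase="post")]
        with pytest.raises(InputError):
            cohort_report(
                animals,
                [{"name": "x", "metric": "swd_per_hr:NREM", "kind": "paired"}],
            )
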