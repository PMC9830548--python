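"""Per-animal seizure/sleep metrics and group-level statistics.

Incidence metrics are exact rational arithmetic on counts and durations
(#/hr, s/hr, % of state time). Group comparisons use classical Student
t-tests (paired or pooled unpaired; Welch optional), one-way ANOVA, and
Holm-Sidak adjustment for pairwise follow-ups. Summaries report
mean +/- SEM with significance flagged at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Hypnogram, InputError, EventInterval
from .staging import StateMetrics

__all__ = [
    "AnimalMetrics",
    "GroupComparison",
    "incidence_metrics",
    "spindle_density",
    "compare_groups",
    "anova_oneway",
    "holm_sidak",
    "cohort_report",
    "CohortResult",
]

ALPHA = 0.05
_STATES = ("wake", "NREM", "REM")


@dataclass
class AnimalMetrics:
    """One animal's (or one phase's) quantified record."""

    animal_id: str
    genotype: str = "het"  # {"wt", "het"}
    sex: str = "M"  # {"M", "F"}
    phase: str = "baseline"  # {"baseline", "pre", "post"}
    duration_h: dict[str, float] = field(default_factory=dict)
    bout_count: dict[str, int] = field(default_factory=dict)
    swd_count: dict[str, int] = field(default_factory=dict)
    swd_total_dur_s: dict[str, float] = field(default_factory=dict)
    swd_per_hr: dict[str, float] = field(default_factory=dict)
    swd_dur_s_per_hr: dict[str, float] = field(default_factory=dict)
    swd_pct_of_state: dict[str, float] = field(default_factory=dict)
    spindle_density_hz: float = 0.0
    nrem_delta_power_mv2_hz: float = float("nan")


def incidence_metrics(
    events: Sequence[EventInterval],
    state_metrics: StateMetrics,
    hyp: Hypnogram,
    animal_id: str = "animal",
    genotype: str = "het",
    sex: str = "M",
    phase: str = "baseline",
    kinds: tuple[str, ...] = ("SWD", "SSWD"),
) -> AnimalMetrics:
    """Per-state discharge counts normalized by time in state.

    ``swd_per_hr = count / hours in state`` and
    ``swd_pct_of_state = total event seconds / state seconds * 100``,
    both exact. Discharge kinds in ``kinds`` are pooled (SWD+SSWD).
    """
    m = AnimalMetrics(animal_id=animal_id, genotype=genotype, sex=sex, phase=phase)
    for state in _STATES:
        dur_s = state_metrics.duration_s.get(state, 0.0)
        evs = [e for e in events if e.kind in kinds and e.state == state]
        count = len(evs)
        total = sum(e.duration_s for e in evs)
        if dur_s == 0 and count > 0:
            raise InputError(f"{count} events in state {state!r} with zero state duration")
        m.duration_h[state] = dur_s / 3600.0
        m.bout_count[state] = state_metrics.bout_count.get(state, 0)
        m.swd_count[state] = count
        m.swd_total_dur_s[state] = total
        if dur_s > 0:
            m.swd_per_hr[state] = count / (dur_s / 3600.0)
            m.swd_dur_s_per_hr[state] = total / (dur_s / 3600.0)
            m.swd_pct_of_state[state] = total / dur_s * 100.0
        else:
            m.swd_per_hr[state] = 0.0
            m.swd_dur_s_per_hr[state] = 0.0
            m.swd_pct_of_state[state] = 0.0
    m.spindle_density_hz = spindle_density(
        [e for e in events if e.kind == "spindle"], hyp
    ) if state_metrics.duration_s.get("NREM", 0) > 0 else 0.0
    return m


def spindle_density(events: Sequence[EventInterval], hyp: Hypnogram) -> float:
    """Spindle count per second of NREM (Hz)."""
    nrem_s = hyp.epoch_seconds("NREM")
    if nrem_s == 0:
        raise InputError("no NREM in hypnogram; spindle density undefined")
    n = sum(1 for e in events if e.kind == "spindle")
    return n / nrem_s


@dataclass
class GroupComparison:
    group_labels: tuple[str, ...]
    n: tuple[int, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    statistic: float
    p_value: float
    test: str
    degenerate: bool = False
    pairwise: "pd.DataFrame | None" = None  # Holm-Sidak follow-up, if any

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Two-sided Student t-test (paired or pooled unpaired; Welch optional).

    A paired comparison of identical vectors has zero variance of the
    differences; it is reported as statistic 0, p = 1 with the
    ``degenerate`` flag rather than raising.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("each group needs n >= 2")
    if paired and len(x) != len(y):
        raise InputError("paired comparison requires equal-length groups")
    degenerate = False
    if paired:
        d = x - y
        if np.all(d == d[0]) and d[0] == 0:
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p = sps.ttest_rel(x, y)
    else:
        if np.std(x) == 0 and np.std(y) == 0 and x.mean() == y.mean():
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return GroupComparison(
        group_labels=labels,
        n=(len(x), len(y)),
        means=(float(x.mean()), float(y.mean())),
        sems=(_sem(x), _sem(y)),
        statistic=float(t),
        p_value=float(p),
        test="paired_t" if paired else "unpaired_t",
        degenerate=degenerate,
    )


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (monotone, >= raw)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, alpha=ALPHA, method="holm-sidak")[1]


def anova_oneway(
    groups: Mapping[str, Sequence[float]],
    pairwise: bool = True,
) -> GroupComparison:
    """One-way ANOVA across groups with optional Holm-Sidak follow-up."""
    labels = tuple(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise InputError("ANOVA needs >= 2 groups with n >= 2 each")
    if all(np.std(g) == 0 for g in arrays) and len({g[0] for g in arrays}) == 1:
        f, p, degenerate = 0.0, 1.0, True
    else:
        f, p = sps.f_oneway(*arrays)
        degenerate = False
        if np.isnan(f):  # identical constant groups
            f, p, degenerate = 0.0, 1.0, True
    pw = None
    if pairwise and len(arrays) >= 2 and not degenerate:
        rows = []
        raw = []
        keys = []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                t, pij = sps.ttest_ind(arrays[i], arrays[j])
                raw.append(float(pij))
                keys.append((labels[i], labels[j]))
                rows.append({"a": labels[i], "b": labels[j], "t": float(t), "p_raw": float(pij)})
        adj = holm_sidak(raw)
        for r, pa in zip(rows, adj):
            r["p_adj"] = float(pa)
            r["significant"] = bool(pa < ALPHA)
        pw = pd.DataFrame(rows)
    return GroupComparison(
        group_labels=labels,
        n=tuple(len(g) for g in arrays),
        means=tuple(float(g.mean()) for g in arrays),
        sems=tuple(_sem(g) for g in arrays),
        statistic=float(f),
        p_value=float(p),
        test="anova_oneway",
        degenerate=degenerate,
        pairwise=pw,
    )


@dataclass
class CohortResult:
    """Mean +/- SEM table and the tests run for each designed comparison."""

    table: pd.DataFrame  # one row per (metric, comparison)
    comparisons: dict[str, GroupComparison]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _metric_value(m: AnimalMetrics, metric: str) -> float:
    if ":" in metric:
        name, state = metric.split(":")
        return float(getattr(m, name)[state])
    return float(getattr(m, metric))


def cohort_report(
    animals: Sequence[AnimalMetrics],
    design: Sequence[Mapping],
) -> CohortResult:
    """Run the designed comparisons over per-animal metrics.

    Each design entry is a dict:
      ``{"name": ..., "metric": "swd_per_hr:NREM" | "nrem_delta_power_mv2_hz" | ...,
         "kind": "unpaired" | "paired" | "anova",
         "split": "genotype" | "sex" | "phase" | "state",
         "filter": {field: value, ...}}``
    ``metric`` may name a per-state dict field as ``field:state``; for
    ``split == "state"`` the metric must be a per-state field and groups
    are its wake/NREM/REM values per animal.
    """
    rows = []
    comps: dict[str, GroupComparison] = {}
    for entry in design:
        name = entry["name"]
        metric = entry["metric"]
        kind = entry["kind"]
        flt = entry.get("filter", {})
        pool = [m for m in animals if all(getattr(m, k) == v for k, v in flt.items())]
        split = entry.get("split")
        if split == "state":
            groups = {s: [getattr(m, metric)[s] for m in pool] for s in _STATES}
            if any(len(v) < 2 for v in groups.values()):
                raise InputError(f"{name}: need >= 2 animals per state cell")
            comp = anova_oneway(groups)
        elif kind == "paired":
            pre = sorted((m for m in pool if m.phase == "pre"), key=lambda m: m.animal_id)
            post = sorted((m for m in pool if m.phase == "post"), key=lambda m: m.animal_id)
            if [m.animal_id for m in pre] != [m.animal_id for m in post]:
                raise InputError(f"{name}: pre/post animals do not pair up")
            comp = compare_groups(
                [_metric_value(m, metric) for m in post],
                [_metric_value(m, metric) for m in pre],
                paired=True,
                labels=("post", "pre"),
            )
        else:
            values: dict[str, list[float]] = {}
            for m in pool:
                values.setdefault(getattr(m, split), []).append(_metric_value(m, metric))
            if len(values) != 2:
                raise InputError(
                    f"{name}: split {split!r} must yield 2 groups, got {sorted(values)}"
                )
            ks = sorted(values)
            comp = compare_groups(values[ks[0]], values[ks[1]], labels=(ks[0], ks[1]))
        comps[name] = comp
        for lab, n, mean, sem in zip(comp.group_labels, comp.n, comp.means, comp.sems):
            rows.append(
                {
                    "comparison": name,
                    "metric": metric,
                    "group": lab,
                    "n": n,
                    "mean": mean,
                    "sem": sem,
                    "test": comp.test,
                    "statistic": comp.statistic,
                    "p": comp.p_value,
                    "significant": comp.significant,
                }
            )
    return CohortResult(table=pd.DataFrame(rows), comparisons=comps)
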