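"""Cohort statistics: group comparisons, Kaplan–Meier and log-rank tests.

Test selection follows a fixed, data-driven rule: Shapiro–Wilk normality
per group at 0.05 chooses between parametric (t-test / one-way ANOVA with
Tukey) and rank tests (Mann–Whitney / Kruskal–Wallis); groups of at least
30 values force the parametric branch regardless.  Survival analyses take
one value per patient (duplicate cores averaged upstream) and use the
standard log-rank (Mantel–Cox) chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

__all__ = [
    "cell_frequency",
    "cell_density",
    "GroupComparison",
    "compare_groups",
    "SurvivalResult",
    "km_logrank",
    "fisher_exact",
]


def cell_frequency(cells: pd.DataFrame, type_column: str = "lineage") -> pd.Series:
    """Per-type percentage of all cells in one image (sums to 100).

    Undefined cells count toward the denominator and get their own entry.
    """
    if len(cells) == 0:
        raise ValueError("empty image")
    return cells[type_column].value_counts(normalize=True).sort_index() * 100.0


def cell_density(
    cells: pd.DataFrame, area_mm2: float, type_column: str = "lineage"
) -> pd.Series:
    """Per-type cells per mm² in one image."""
    if area_mm2 <= 0:
        raise ValueError("image area must be positive")
    return cells[type_column].value_counts().sort_index() / area_mm2


@dataclass
class GroupComparison:
    feature: str
    groups: list
    test: str
    p_value: float
    statistic: float
    paired: bool = False
    normal: bool | None = None
    pairwise: pd.DataFrame | None = field(default=None, repr=False)


def _all_normal(groups: Sequence[np.ndarray], alpha: float) -> bool:
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            return False
        if stats.shapiro(g).pvalue < alpha:
            return False
    return True


def compare_groups(
    values_by_group: Mapping,
    paired: bool = False,
    feature: str = "",
    normality_alpha: float = 0.05,
    large_n: int = 30,
) -> GroupComparison:
    """Two-group or multi-group comparison with rule-based test selection.

    Parametric when every group passes Shapiro–Wilk at ``normality_alpha``
    or when every group has at least ``large_n`` values (the large-sample
    override).  Two groups: Student's t (paired or unpaired) vs
    Mann–Whitney (Wilcoxon signed-rank when paired).  More than two
    groups: one-way ANOVA with Tukey's pairwise comparisons, or
    Kruskal–Wallis.  Two-sided throughout.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups with at least two values each")
    large = all(len(g) >= large_n for g in groups)
    normal = _all_normal(groups, normality_alpha)
    parametric = normal or large

    pairwise = None
    if len(groups) == 2:
        a, b = groups
        if parametric:
            if paired:
                res = stats.ttest_rel(a, b)
                test = "paired t-test"
            else:
                res = stats.ttest_ind(a, b)
                test = "t-test"
        else:
            if paired:
                res = stats.wilcoxon(a, b)
                test = "Wilcoxon signed-rank"
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                test = "Mann-Whitney"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            raise NotImplementedError("paired designs support two groups only")
        if parametric:
            res = stats.f_oneway(*groups)
            test = "one-way ANOVA"
            tk = stats.tukey_hsd(*groups)
            rows = []
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    rows.append(
                        {
                            "group_a": names[i],
                            "group_b": names[j],
                            "p_value": float(tk.pvalue[i, j]),
                        }
                    )
            pairwise = pd.DataFrame(rows)
        else:
            res = stats.kruskal(*groups)
            test = "Kruskal-Wallis"
        stat, p = float(res.statistic), float(res.pvalue)

    if np.isnan(p):  # identical constant groups under a t-test
        p = 1.0
    return GroupComparison(
        feature=feature,
        groups=names,
        test=test,
        p_value=p,
        statistic=stat,
        paired=paired,
        normal=normal,
        pairwise=pairwise,
    )


@dataclass
class SurvivalResult:
    stratification: str
    group_sizes: dict
    statistic: float
    p_value: float
    curves: dict = field(repr=False)


def km_logrank(
    groups: Mapping[str, Sequence[str]],
    clinical: pd.DataFrame,
    stratification: str = "",
) -> SurvivalResult:
    """Kaplan–Meier curves and log-rank test over disjoint patient groups.

    ``clinical`` must be patient-level (one row per patient, columns
    ``patient_id``, ``overall_survival_days``, ``event``); ``groups`` maps
    group name to patient ids.  Two groups use the standard 1-df log-rank
    chi-square; more use the k-sample multivariate form.
    """
    clin = clinical.set_index(clinical["patient_id"].astype(str))
    seen: set = set()
    durations, events, labels = [], [], []
    curves = {}
    for name, pids in groups.items():
        pids = [str(p) for p in pids]
        overlap = seen & set(pids)
        if overlap:
            raise ValueError(f"patients in multiple groups: {sorted(overlap)}")
        seen |= set(pids)
        sub = clin.loc[pids]
        if len(sub) and not sub["event"].astype(bool).any():
            warnings.warn(f"group {name!r} has no observed events", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["overall_survival_days"], sub["event"].astype(bool), label=str(name))
        curves[name] = kmf.survival_function_
        durations.append(sub["overall_survival_days"].to_numpy(dtype=float))
        events.append(sub["event"].astype(bool).to_numpy())
        labels.append(np.full(len(sub), str(name), dtype=object))

    if len(groups) == 2:
        (d1, d2), (e1, e2) = durations, events
        res = logrank_test(d1, d2, event_observed_A=e1, event_observed_B=e2)
    else:
        res = multivariate_logrank_test(
            np.concatenate(durations), np.concatenate(labels), np.concatenate(events)
        )
    return SurvivalResult(
        stratification=stratification,
        group_sizes={k: len(v) for k, v in groups.items()},
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2×2 contingency table."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
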