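"""Adaptive hypothesis-test selection for per-cell measurement tables.

The decision procedure mirrors common practice in quantitative cell
biology: with at least 30 measurements per group the parametric tests
are used directly (two-sample t-test for two groups, one-way ANOVA with
Tukey-Kramer posthoc for more); with smaller samples each group is
first screened for normality with an Anderson-Darling test, and any
departure switches the comparison to rank-based tests (Wilcoxon rank
sum for two groups, Kruskal-Wallis with Dunn posthoc and Sidak
adjustment for more).  Whenever a one-way ANOVA would run, variance
homogeneity is checked first with Levene's test (Brown-Forsythe
median-centred variant by default) and unequal variances divert to
Kruskal-Wallis.  Every decision records the full branch provenance.

Dunn's posthoc z-statistics are computed directly from the pooled-rank
sums with tie correction (no established Python package ships this
posthoc), and adjusted with the Sidak formula.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "BranchRecord",
    "StatDecision",
    "RegressionResult",
    "GeometryContrast",
    "choose_and_run_test",
    "dunn_sidak_posthoc",
    "linear_regression",
    "geometry_contrast",
]


@dataclass(frozen=True)
class BranchRecord:
    """Which branch of the decision tree was taken and why."""

    n_min: int
    n_groups: int
    normality_p: dict[str, float] | None
    variance_homogeneity_p: float | None
    test_chosen: str
    posthoc: str | None
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class StatDecision:
    """Outcome of the adaptive procedure for one comparison."""

    branch: BranchRecord
    statistic: float
    p_value: float
    posthoc_pvalues: dict[tuple[str, str], float] | None
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares line and Pearson r of the pairs."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GeometryContrast:
    """Geometry comparison: medians, pairwise percent differences of
    medians (relative to the second label of each pair), and the
    adaptive test's decision."""

    decision: StatDecision
    medians: dict[str, float]
    percent_difference: dict[tuple[str, str], float]
    n_per_group: dict[str, int] = field(default_factory=dict)


def _validate_groups(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None
) -> tuple[list[np.ndarray], list[str]]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.ndim != 1 or arr.size < 3:
            raise ValueError("each group needs at least 3 numeric values")
        if not np.all(np.isfinite(arr)):
            raise ValueError("groups must contain finite numeric values")
        arrays.append(arr)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    elif len(labels) != len(arrays):
        raise ValueError("labels and groups lengths differ")
    return arrays, list(labels)


def dunn_sidak_posthoc(
    groups: Sequence[np.ndarray], labels: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on pooled ranks, Sidak-adjusted.

    Uses the tie-corrected variance N(N+1)/12 - sum(t^3 - t)/(12(N-1));
    the Sidak adjustment is 1 - (1 - p)^m over the m pairs.
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + g.size].mean()))
        sizes.append(g.size)
        start += g.size
    m = len(groups) * (len(groups) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out[(labels[i], labels[j])] = float(1.0 - (1.0 - p) ** m)
    return out


def _tukey_posthoc(
    groups: Sequence[np.ndarray], labels: Sequence[str]
) -> dict[tuple[str, str], float]:
    res = sps.tukey_hsd(*groups)
    return {
        (labels[i], labels[j]): float(res.pvalue[i, j])
        for i, j in itertools.combinations(range(len(groups)), 2)
    }


def choose_and_run_test(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    welch: bool = False,
    levene_center: str = "median",
) -> StatDecision:
    """Select and run the comparison dictated by the decision tree.

    Branches: (i) min n >= 30 -> t-test (2 groups) or one-way ANOVA with
    Tukey-Kramer (more); (ii) min n < 30 -> Anderson-Darling normality
    screen per group at ``alpha``; all normal -> as (i), any non-normal
    -> Wilcoxon rank sum (2 groups) or Kruskal-Wallis + Dunn-Sidak;
    (iii) before any ANOVA, Levene's test at ``alpha`` (median-centred
    by default); unequal variances -> Kruskal-Wallis + Dunn-Sidak.
    """
    arrays, names = _validate_groups(groups, labels)
    n_min = min(a.size for a in arrays)
    n_groups = len(arrays)
    notes: list[str] = []

    normality_p: dict[str, float] | None = None
    parametric = True
    if n_min < 30:
        normality_p = {}
        for name, arr in zip(names, arrays):
            _, p_norm = normal_ad(arr)
            normality_p[name] = float(p_norm)
        parametric = all(p > alpha for p in normality_p.values())
        notes.append(
            "all groups pass Anderson-Darling normality"
            if parametric
            else "Anderson-Darling rejects normality for at least one group"
        )
    else:
        notes.append("min n >= 30: parametric branch without normality screen")

    variance_p: float | None = None
    posthoc_p: dict[tuple[str, str], float] | None = None

    if parametric and n_groups == 2:
        stat, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
        test = "welch-t" if welch else "student-t"
        posthoc_name = None
    elif parametric:
        _, variance_p = sps.levene(*arrays, center=levene_center)
        variance_p = float(variance_p)
        if variance_p <= alpha:
            notes.append("Levene rejects equal variances: Kruskal-Wallis instead of ANOVA")
            stat, p = sps.kruskal(*arrays)
            test, posthoc_name = "kruskal-wallis", "dunn-sidak"
            posthoc_p = dunn_sidak_posthoc(arrays, names)
        else:
            stat, p = sps.f_oneway(*arrays)
            test, posthoc_name = "anova", "tukey-kramer"
            posthoc_p = _tukey_posthoc(arrays, names)
    elif n_groups == 2:
        stat, p = sps.ranksums(arrays[0], arrays[1])
        test, posthoc_name = "wilcoxon-ranksum", None
    else:
        stat, p = sps.kruskal(*arrays)
        test, posthoc_name = "kruskal-wallis", "dunn-sidak"
        posthoc_p = dunn_sidak_posthoc(arrays, names)

    branch = BranchRecord(
        n_min=n_min,
        n_groups=n_groups,
        normality_p=normality_p,
        variance_homogeneity_p=variance_p,
        test_chosen=test,
        posthoc=posthoc_name,
        notes=tuple(notes),
    )
    return StatDecision(
        branch=branch,
        statistic=float(stat),
        p_value=float(p),
        posthoc_pvalues=posthoc_p,
        alpha=alpha,
    )


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS slope/intercept and Pearson r of paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.var(x) == 0:
        raise ValueError("x is constant: regression undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def geometry_contrast(
    table: pd.DataFrame,
    by: str = "geometry_label",
    metric: str = "nc_ratio",
    alpha: float = 0.05,
) -> GeometryContrast:
    """Compare a per-cell metric between geometry groups.

    Groups are formed from the ``by`` column (the caller restricts the
    table to matched pattern areas when several are present); the
    adaptive test runs over the groups and the percent difference of
    group medians is reported for each ordered pair, relative to the
    second label.
    """
    if by not in table.columns or metric not in table.columns:
        raise KeyError(f"table must have columns {by!r} and {metric!r}")
    grouped = {str(k): v[metric].to_numpy(dtype=float) for k, v in table.groupby(by)}
    if len(grouped) < 2:
        raise ValueError("need at least 2 geometry groups for a contrast")
    labels = sorted(grouped)
    arrays = [grouped[k] for k in labels]
    decision = choose_and_run_test(arrays, alpha=alpha, labels=labels)
    medians = {k: float(np.median(grouped[k])) for k in labels}
    pct = {
        (a, b): 100.0 * (medians[a] - medians[b]) / medians[b]
        for a, b in itertools.combinations(labels, 2)
    }
    return GeometryContrast(
        decision=decision,
        medians=medians,
        percent_difference=pct,
        n_per_group={k: int(grouped[k].size) for k in labels},
    )
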