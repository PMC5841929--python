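"""Two-group statistical comparisons and report tables.

Unit-level metrics (rates, CSI, burst and ISI statistics) are compared
with the two-sided Mann-Whitney U test (equivalently Wilcoxon rank-sum);
proportions with Pearson's chi-square on the 2x2 table (1 d.f., no
continuity correction); per-animal ripple summaries with one-way ANOVA.
Significance stars follow the usual convention: * p<0.05, ** p<0.01,
*** p<0.001. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError


@dataclass
class GroupComparison:
    metric: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    test: str
    statistic: float
    p: float
    stars: str


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def sem(x) -> float:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def mann_whitney(a, b):
    """Two-sided Mann-Whitney U (exact for n <= 20 without ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be nonempty")
    method = "exact" if (len(a) <= 20 and len(b) <= 20
                         and len(np.unique(np.concatenate([a, b])))
                         == len(a) + len(b)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


#: the paper's naming varies; both refer to the same test
wilcoxon_ranksum = mann_whitney


def chi_square_proportions(k1: int, n1: int, k2: int, n2: int):
    """Pearson chi-square on the 2x2 proportion table, 1 d.f.,
    no continuity correction."""
    if min(k1, k2) < 0 or k1 > n1 or k2 > n2:
        raise DataError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DataError("chi-square undefined with a zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups):
    """Standard one-way F test (used on per-animal means)."""
    cleaned = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if len(g) < 2:
            raise DataError("each group needs >=2 values")
        cleaned.append(g)
    if len(cleaned) < 2:
        raise DataError("need >=2 groups")
    res = stats.f_oneway(*cleaned)
    return float(res.statistic), float(res.pvalue)


def compare_metric(metric: str, a, b, test: str = "mwu") -> GroupComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    af = a[np.isfinite(a)]
    bf = b[np.isfinite(b)]
    if test in ("mwu", "ranksum"):
        statistic, p = mann_whitney(af, bf)
        name = "Mann-Whitney U"
    elif test == "anova1":
        statistic, p = one_way_anova(af, bf)
        name = "one-way ANOVA"
    else:
        raise DataError(f"unknown test {test!r}")
    return GroupComparison(metric, float(np.mean(af)), sem(af), len(af),
                           float(np.mean(bf)), sem(bf), len(bf),
                           name, statistic, p, significance_stars(p))


def build_report(metrics_a: dict, metrics_b: dict,
                 tests: dict = None) -> pd.DataFrame:
    """Comparison table over shared metrics of two groups.

    ``metrics_a``/``metrics_b`` map metric name -> sample array (per unit
    or per animal, depending on the metric); ``tests`` optionally maps
    metric name -> 'mwu' | 'anova1' (default 'mwu'). Metrics missing from
    either group are omitted with a warning column-free row skip.
    """
    tests = tests or {}
    rows = []
    for metric in metrics_a:
        if metric not in metrics_b:
            continue
        try:
            c = compare_metric(metric, metrics_a[metric], metrics_b[metric],
                               tests.get(metric, "mwu"))
        except DataError:
            continue
        rows.append(vars(c))
    return pd.DataFrame(rows)
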