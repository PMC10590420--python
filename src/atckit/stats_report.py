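"""Statistical layer: normality-gated two-group tests, box-plot summaries,
and metric–marker correlations across conditions.

Group comparisons follow the convention of normality-gated testing: each
group is checked with Shapiro–Wilk at alpha = 0.05; when both pass, a
two-sample Welch t-test is used, otherwise the nonparametric Mann–Whitney U.
Correlation across conditions pairs the per-condition median of a
displacement metric with the median marker intensity; with only a handful of
condition points the coefficient is reported descriptively (no p-value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "CorrelationResult", "compare_groups",
           "box_summary", "metric_marker_correlation"]

ALPHA = 0.05


@dataclass
class TestResult:
    """Two-group comparison outcome."""

    test_name: str          # "t_test" or "mann_whitney"
    statistic: float
    p_value: float
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class CorrelationResult:
    """Correlation of paired per-condition medians."""

    pearson_r: float
    spearman_r: float
    n: int
    table: pd.DataFrame     # condition, metric_median, marker_median


def compare_groups(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Compare two samples with a normality-gated two-sample test.

    Both groups normal by Shapiro–Wilk (alpha = 0.05) => Welch two-sample
    t-test; otherwise Mann–Whitney U (two-sided).  Requires n >= 3 per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    normal_a = _is_normal(a)
    normal_b = _is_normal(b)
    if normal_a and normal_b:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        name = "t_test"
    else:
        method = "exact" if max(a.size, b.size) <= 8 else "auto"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
        name = "mann_whitney"
    return TestResult(test_name=name, statistic=float(stat),
                      p_value=float(p), n1=a.size, n2=b.size)


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False    # degenerate sample; Shapiro is undefined
    return stats.shapiro(x).pvalue >= ALPHA


def box_summary(sample: np.ndarray) -> tuple[float, float, float, float, float]:
    """(q25, median, q75, p1, p99) with linear percentile interpolation.

    The whisker convention is the 1st and 99th percentile.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q25, med, q75, p1, p99 = np.percentile(x, [25, 50, 75, 1, 99])
    return float(q25), float(med), float(q75), float(p1), float(p99)


def metric_marker_correlation(metric_medians: np.ndarray,
                              marker_medians: np.ndarray,
                              conditions: list | None = None
                              ) -> CorrelationResult:
    """Correlate per-condition metric medians with marker medians.

    Pearson r is the primary coefficient; Spearman rank correlation is
    reported alongside.  With the few condition points available the
    coefficients are descriptive (no p-value is attached).  Zero variance in
    either variable makes the correlation undefined and raises ``ValueError``.
    """
    x = np.asarray(metric_medians, dtype=float)
    y = np.asarray(marker_medians, dtype=float)
    if x.size != y.size:
        raise ValueError("paired medians must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 paired condition medians")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    table = pd.DataFrame({
        "condition": conditions if conditions is not None else range(x.size),
        "metric_median": x, "marker_median": y})
    return CorrelationResult(pearson_r=pearson, spearman_r=spearman,
                             n=x.size, table=table)
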