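"""Statistical tests for senescence time-course and endpoint data.

Per-series ordinary least-squares fits, an ANCOVA-style comparison of the
slopes of two time series, Benjamini–Hochberg FDR adjustment, one-way ANOVA,
Student's pooled-variance t-test, and a Bonferroni multiple-range comparison
of group means (as used for per-cell relative-telomere-length values).

All tests are two-sided unless stated otherwise. Degenerate inputs with zero
residual variance use the conventions documented on each function rather than
returning NaN.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LinearFit",
    "SlopeComparison",
    "MultipleRangeResult",
    "PairwiseComparison",
    "fit_linear",
    "compare_timeseries_ancova",
    "bh_fdr",
    "one_way_anova",
    "students_t",
    "multiple_range_bonferroni",
]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares fit of values against time.

    ``goodness_of_fit`` is the coefficient of determination R²; for a
    constant response (zero total sum of squares) a zero-residual fit is
    reported as R² = 1.
    """

    slope: float
    intercept: float
    slope_se: float
    residual_variance: float
    n: int
    goodness_of_fit: float


@dataclass(frozen=True)
class SlopeComparison:
    """Slope-equality test between two independently fitted time series."""

    delta_slope: float
    test_statistic: float
    dof: int
    p_value: float
    significant: bool
    alpha: float
    delta_intercept: float
    intercept_p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[int, int]
    t_statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class MultipleRangeResult:
    group_means: tuple[float, ...]
    comparisons: tuple[PairwiseComparison, ...]
    alpha: float
    adjusted_alpha: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def fit_linear(times: Sequence[float], values: Sequence[float]) -> LinearFit:
    """Fit ``values = intercept + slope * times`` by ordinary least squares.

    Requires at least two observations at two distinct times. The slope
    standard error uses the unbiased residual variance SSE/(n-2); with n = 2
    the residual variance is reported as 0 and the standard error as 0.
    """
    t = _as_1d(times, "times")
    y = _as_1d(values, "values")
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    n = t.size
    if n < 2:
        raise ValueError("at least 2 observations are required")
    sxx = float(np.sum((t - t.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("all time values are identical; slope is undefined")
    sxy = float(np.sum((t - t.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    resid_var = sse / (n - 2) if n > 2 else 0.0
    slope_se = math.sqrt(resid_var / sxx)
    if sst > 0.0:
        r2 = max(0.0, min(1.0, 1.0 - sse / sst))
    else:
        r2 = 1.0 if sse <= 1e-300 else 0.0
    return LinearFit(slope, intercept, slope_se, resid_var, n, r2)


def _fit_sums(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Return (slope, intercept, SSE, Sxx) for one series."""
    fit = fit_linear(t, y)
    resid = y - (fit.intercept + fit.slope * t)
    sxx = float(np.sum((t - t.mean()) ** 2))
    return fit.slope, fit.intercept, float(resid @ resid), sxx


def compare_timeseries_ancova(
    times_a: Sequence[float],
    values_a: Sequence[float],
    times_b: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
) -> SlopeComparison:
    """Compare the slopes of two time series fitted independently.

    Each series gets its own ordinary least-squares line; the slope
    difference is tested with a t statistic using the residual variance
    pooled across both fits, on ``n_a + n_b - 4`` degrees of freedom. The
    intercept difference is tested the same way and reported secondarily.

    Conventions for degenerate data (zero pooled residual variance): equal
    slopes give p = 1, unequal slopes give p = 0 with ``degenerate=True``.
    """
    ta = _as_1d(times_a, "times_a")
    ya = _as_1d(values_a, "values_a")
    tb = _as_1d(times_b, "times_b")
    yb = _as_1d(values_b, "values_b")
    if ta.size < 2 or tb.size < 2 or ta.size + tb.size < 5:
        raise ValueError("need >= 2 points per series and >= 5 overall for a pooled-variance slope test")
    slope_a, int_a, sse_a, sxx_a = _fit_sums(ta, ya)
    slope_b, int_b, sse_b, sxx_b = _fit_sums(tb, yb)
    dof = ta.size + tb.size - 4
    pooled = (sse_a + sse_b) / dof
    delta = slope_a - slope_b
    delta_int = int_a - int_b
    se = math.sqrt(pooled * (1.0 / sxx_a + 1.0 / sxx_b))
    se_int = math.sqrt(
        pooled
        * (1.0 / ta.size + ta.mean() ** 2 / sxx_a + 1.0 / tb.size + tb.mean() ** 2 / sxx_b)
    )
    if se == 0.0:
        if delta == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, delta), 0.0
        p_int = 1.0 if delta_int == 0.0 else 0.0
        return SlopeComparison(delta, t_stat, dof, p, p < alpha, alpha, delta_int, p_int, True)
    t_stat = delta / se
    p = 2.0 * float(sps.t.sf(abs(t_stat), dof))
    t_int = delta_int / se_int if se_int > 0 else 0.0
    p_int = 2.0 * float(sps.t.sf(abs(t_int), dof)) if se_int > 0 else 1.0
    return SlopeComparison(delta, t_stat, dof, p, p < alpha, alpha, delta_int, p_int, False)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q-values are monotone non-decreasing in p and the procedure is idempotent
    on an already-adjusted vector.
    """
    p = _as_1d(p_values, "p_values")
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Returns ``(F, (df_between, df_within), p)``. When all groups are
    identical (both mean squares zero) F = 0 and p = 1; when the groups are
    internally constant but differ (zero within-group variance) F = inf and
    p = 0.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least 2 observations")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    grand = float(np.concatenate(arrs).mean())
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    dof = (k - 1, n_total - k)
    if ss_between <= 1e-300:
        return 0.0, dof, 1.0
    if ss_within <= 1e-300:
        return math.inf, dof, 0.0
    f_stat, p = sps.f_oneway(*arrs)
    return float(f_stat), dof, float(p)


def students_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided pooled-variance (Student's) two-sample t-test.

    Returns ``(t, dof, p)``. Zero pooled variance: equal means give
    (0, dof, 1); unequal means give a signed infinite t with p = 0.
    """
    xa = _as_1d(a, "a")
    xb = _as_1d(b, "b")
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    dof = xa.size + xb.size - 2
    sp2 = (np.sum((xa - xa.mean()) ** 2) + np.sum((xb - xb.mean()) ** 2)) / dof
    diff = float(xa.mean() - xb.mean())
    if sp2 <= 1e-300:
        if diff == 0.0:
            return 0.0, dof, 1.0
        return math.copysign(math.inf, diff), dof, 0.0
    t_stat, p = sps.ttest_ind(xa, xb, equal_var=True)
    return float(t_stat), dof, float(p)


def multiple_range_bonferroni(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> MultipleRangeResult:
    """All-pairs pooled t-tests with a Bonferroni-adjusted threshold.

    With m groups there are m(m-1)/2 pairs; a pair is flagged significant
    when its raw two-sided p is below ``alpha / n_pairs``.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    n_pairs = len(arrs) * (len(arrs) - 1) // 2
    adj_alpha = alpha / n_pairs
    comps = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        t_stat, _, p = students_t(arrs[i], arrs[j])
        comps.append(PairwiseComparison((i, j), t_stat, p, p < adj_alpha))
    means = tuple(float(a.mean()) for a in arrs)
    return MultipleRangeResult(means, tuple(comps), alpha, adj_alpha)
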