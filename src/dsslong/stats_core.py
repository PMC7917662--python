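"""Statistical primitives shared by every analysis stage.

Thin, validated wrappers around scipy/statsmodels: Pearson correlation with a
two-tailed p-value, simple linear regression, one- and two-way ANOVA, and the
permutation p-value rule used by distance-based tests.

Degenerate inputs (constant vectors) are surfaced as explicitly tagged
"undefined" results rather than NaNs, so downstream screens can treat an
absent or flat taxon as not-selected instead of silently propagating NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "CorrelationResult",
    "RegressionFit",
    "AnovaResult",
    "TwoWayAnovaResult",
    "pearson",
    "linear_regression",
    "anova_oneway",
    "anova_twoway",
    "permutation_pvalue",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation coefficient with its two-tailed p-value.

    ``defined`` is False when either input vector is constant, in which case
    ``r`` and ``p`` are NaN and the result must not be treated as significant.
    """

    r: float
    p: float
    n: int
    defined: bool = True

    def significant(self, r_threshold: float, p_threshold: float) -> bool:
        """Strict |r| > r_threshold and p < p_threshold; False if undefined."""
        if not self.defined:
            return False
        return abs(self.r) > r_threshold and self.p < p_threshold


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float


@dataclass(frozen=True)
class TwoWayAnovaResult:
    """Main-effect and interaction F/p for a balanced two-factor design."""

    F_a: float
    p_a: float
    F_b: float
    p_b: float
    F_ab: float | None
    p_ab: float | None
    ss_a: float
    ss_b: float
    ss_ab: float | None
    ss_error: float


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with two-tailed p from the t transform.

    p is computed from t = r*sqrt((n-2)/(1-r^2)) against Student's t with
    n-2 degrees of freedom. A constant input yields a tagged undefined
    result instead of an error so screening loops can skip flat taxa.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    n = int(xv.size)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(math.nan, math.nan, n, defined=False)
    res = scipy.stats.pearsonr(xv, yv)
    r = float(res.statistic)
    # exact linear dependence: p underflows to 0; clamp into (0, 1]
    p = float(res.pvalue)
    if p == 0.0:
        p = float(np.nextafter(0.0, 1.0))
    return CorrelationResult(r, p, n)


def linear_regression(x, y) -> RegressionFit:
    """Ordinary least squares y = slope*x + intercept with R^2."""
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant; regression undefined")
    res = scipy.stats.linregress(xv, yv)
    if np.ptp(yv) == 0:
        r2 = 1.0  # flat response fit exactly by slope 0
    else:
        r2 = float(res.rvalue**2)
    return RegressionFit(float(res.slope), float(res.intercept), r2)


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way ANOVA over >=2 groups of >=2 observations each."""
    arrs = [_as_vector(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least 2 observations")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    n = all_vals.size
    k = len(arrs)
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else math.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(scipy.stats.f.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0
    return AnovaResult(float(f), p, df_b, df_w, ss_between, ss_within)


def anova_twoway(values, factor_a, factor_b) -> TwoWayAnovaResult:
    """Two-way ANOVA on a balanced complete design (e.g. dose x day).

    With >1 replicate per cell the interaction term is fitted; with exactly
    one replicate the additive model is used and no interaction is reported.
    Unbalanced designs are rejected — aggregate to cell means first.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = _as_vector(values, "values")
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    df = pd.DataFrame({"y": y, "a": fa.astype(str), "b": fb.astype(str)})
    cells = df.groupby(["a", "b"]).size()
    n_a, n_b = df["a"].nunique(), df["b"].nunique()
    if len(cells) != n_a * n_b or cells.nunique() != 1:
        raise ValueError(
            "unbalanced or incomplete design; aggregate to cell means first"
        )
    reps = int(cells.iloc[0])
    formula = "y ~ C(a) * C(b)" if reps > 1 else "y ~ C(a) + C(b)"
    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    # SS at floating-point-noise level relative to the response magnitude
    # (exact fits, constant responses) must not produce arbitrary F ratios
    ss_floor = 1e-20 * max(1.0, float(np.abs(y).max()) ** 2) * y.size

    def _row(name):
        row = tab.loc[name]
        f = float(row["F"])
        p = float(row["PR(>F)"])
        if math.isnan(f) or float(row["sum_sq"]) <= ss_floor:
            f, p = 0.0, 1.0
        return f, p, float(row["sum_sq"])

    f_a, p_a, ss_a = _row("C(a)")
    f_b, p_b, ss_b = _row("C(b)")
    ss_err = float(tab.loc["Residual", "sum_sq"])
    if reps > 1:
        f_ab, p_ab, ss_ab = _row("C(a):C(b)")
    else:
        f_ab = p_ab = ss_ab = None
    return TwoWayAnovaResult(f_a, p_a, f_b, p_b, f_ab, p_ab, ss_a, ss_b, ss_ab, ss_err)


def permutation_pvalue(observed: float, null_stats) -> float:
    """p = (1 + #{null >= observed}) / (1 + B); never exactly zero."""
    nulls = np.asarray(null_stats, dtype=float)
    if nulls.size == 0:
        raise ValueError("null_stats must be non-empty")
    return float((1 + int(np.sum(nulls >= observed))) / (1 + nulls.size))
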