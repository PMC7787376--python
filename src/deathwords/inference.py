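"""Statistical layer: paired/independent comparisons, correlation,
multiplicity control, power analysis and hierarchical regression.

Effect-size conventions
-----------------------
* Paired designs report Cohen's d_z: mean of the within-pair differences
  divided by their standard deviation, so ``d_z * sqrt(n) == t`` exactly.
  Its sign follows the sign of ``mean(x) - mean(y)``.
* Independent designs report pooled-SD Cohen's d with the same sign
  convention, and use the Welch-Satterthwaite test by default.

Power for the paired t is computed from the noncentral t distribution
with noncentrality ``d * sqrt(n)`` and ``n - 1`` degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "bonferroni_alpha",
    "format_alpha",
    "paired_t",
    "independent_t",
    "pearson_r",
    "required_n_paired",
    "paired_power",
    "hier_regression",
    "PairedTestResult",
    "IndependentTestResult",
    "CorrelationResult",
    "PowerSpec",
    "HierRegressionResult",
    "BlockFit",
]


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Per-comparison significance level alpha / k at full precision."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def format_alpha(alpha: float, decimals: int = 4) -> str:
    """Display form of a level, truncated (not rounded) as in reports.

    ``format_alpha(.05 / 3)`` -> ``".0166"``.  Truncation is
    presentation only; comparisons must use the full-precision value.
    """
    scale = 10 ** decimals
    truncated = math.floor(alpha * scale) / scale
    return f"{truncated:.{decimals}f}".lstrip("0")


def _t_ci(estimate: float, se: float, df: float, level: float) -> tuple[float, float]:
    half = stats.t.ppf(0.5 + level / 2, df) * se
    return (estimate - half, estimate + half)


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    mean_a: float
    mean_b: float
    mean_diff: float
    se_diff: float
    ci: tuple[float, float]
    t: float
    df: int
    p: float
    cohen_d: float          # d_z = mean_diff / sd_diff; NaN when degenerate
    degenerate: bool = False


def paired_t(x, y, ci_level: float = 0.95) -> PairedTestResult:
    """Classic paired-samples t-test on within-pair differences.

    Pairs with an undefined member are dropped; at least two complete
    pairs are required.  Zero-variance differences yield a degenerate
    result (t/p/d undefined-as-NaN, flagged) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise ValueError("fewer than 2 complete pairs")
    diff = x - y
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    df = n - 1
    if sd_diff == 0.0:
        return PairedTestResult(
            n, float(x.mean()), float(y.mean()), mean_diff, 0.0,
            (mean_diff, mean_diff), np.nan, df, np.nan, np.nan, degenerate=True,
        )
    se = sd_diff / math.sqrt(n)
    t = mean_diff / se
    p = 2 * stats.t.sf(abs(t), df)
    d_z = mean_diff / sd_diff
    return PairedTestResult(
        n, float(x.mean()), float(y.mean()), mean_diff, se,
        _t_ci(mean_diff, se, df, ci_level), t, df, float(p), d_z,
    )


@dataclass(frozen=True)
class IndependentTestResult:
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    mean_diff: float
    se_diff: float
    ci: tuple[float, float]
    t: float
    df: float               # fractional under Welch
    p: float
    cohen_d: float          # pooled-SD Cohen's d, sign of (mean1 - mean2)
    welch: bool


def independent_t(x, y, welch: bool = True, ci_level: float = 0.95) -> IndependentTestResult:
    """Two-sample t-test (Welch-Satterthwaite by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = float(x.var(ddof=1)), float(y.var(ddof=1))
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("degenerate: zero variance in both groups")
    mean_diff = float(x.mean() - y.mean())
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
    se = math.sqrt(se2)
    t = mean_diff / se
    p = 2 * stats.t.sf(abs(t), df)
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = mean_diff / sp if sp > 0 else np.nan
    return IndependentTestResult(
        n1, n2, float(x.mean()), float(y.mean()), math.sqrt(v1), math.sqrt(v2),
        mean_diff, se, _t_ci(mean_diff, se, df, ci_level), t, float(df), float(p),
        d, welch,
    )


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    t: float
    df: int
    p: float


def pearson_r(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-tailed p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("fewer than 3 complete pairs")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(n, r, math.inf * np.sign(r), df, 0.0)
    t = r * math.sqrt(df / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df)
    return CorrelationResult(n, r, t, df, float(p))


@dataclass(frozen=True)
class PowerSpec:
    """A priori power specification for a two-tailed paired t-test."""

    d: float
    alpha: float
    power: float
    n: int | None = None
    achieved_power: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.d == 0:
            raise ValueError("effect size d must be non-zero")


def paired_power(d: float, n: int, alpha: float) -> float:
    """Two-tailed paired-t power from the noncentral t distribution."""
    df = n - 1
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    ncp = abs(d) * math.sqrt(n)
    return float(1 - stats.nct.cdf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp))


def required_n_paired(spec: PowerSpec, n_max: int = 10_000_000) -> PowerSpec:
    """Smallest n whose paired-t power reaches the target.

    Iterates n upward from 2, computing power from the noncentral t with
    noncentrality ``d * sqrt(n)`` and ``df = n - 1``; the returned spec
    carries the minimal n and its achieved power.
    """
    # bracket by doubling, then binary-search: power is monotone in n
    lo, hi = 2, 2
    while paired_power(spec.d, hi, spec.alpha) < spec.power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("target power unreachable within n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_power(spec.d, mid, spec.alpha) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return PowerSpec(spec.d, spec.alpha, spec.power, n=lo,
                     achieved_power=paired_power(spec.d, lo, spec.alpha))


@dataclass(frozen=True)
class BlockFit:
    r2: float
    f: float
    df_model: int
    df_resid: int
    p: float


@dataclass(frozen=True)
class HierRegressionResult:
    """Two-block hierarchical OLS fit.

    ``coefficients`` is indexed by predictor (plus ``const``) with
    columns estimate / se / ci_low / ci_high / p / semipartial; the
    semipartial correlation of a final-model predictor is the signed
    square root of the R-squared drop when that predictor alone is
    removed.
    """

    block1: BlockFit
    block2: BlockFit
    delta_r2: float
    delta_f: float
    delta_p: float
    coefficients: "object"  # pandas DataFrame

    @property
    def r2_full(self) -> float:
        return self.block2.r2


def _ols(y, X):
    model = sm.OLS(y, X, missing="raise")
    return model.fit()


def hier_regression(table, outcome: str, block1: list[str], block2: list[str],
                    ci_level: float = 0.95) -> HierRegressionResult:
    """Hierarchical (two-block) multiple linear regression.

    Fits OLS of ``outcome`` on block-1 predictors, then on block 1 +
    block 2, and tests the block-2 increment with the nested-model F
    test.  Requires complete rows for the listed variables (run it per
    imputed copy and pool for incomplete data).
    """
    import pandas as pd

    cols = [outcome, *block1, *block2]
    data = table[cols].dropna()
    n = len(data)
    if n <= len(block1) + len(block2) + 2:
        raise ValueError("too few complete rows for the requested model")
    y = data[outcome].to_numpy(dtype=float)

    def design(preds):
        X = sm.add_constant(data[list(preds)].astype(float), has_constant="add")
        return X

    fit1 = _ols(y, design(block1))
    fit2 = _ols(y, design(block1 + block2))
    if fit2.df_resid <= 0 or np.linalg.matrix_rank(design(block1 + block2)) < len(block1) + len(block2) + 1:
        raise ValueError("rank-deficient design")

    b1 = BlockFit(float(fit1.rsquared), float(fit1.fvalue), int(fit1.df_model),
                  int(fit1.df_resid), float(fit1.f_pvalue))
    b2 = BlockFit(float(fit2.rsquared), float(fit2.fvalue), int(fit2.df_model),
                  int(fit2.df_resid), float(fit2.f_pvalue))
    delta_r2 = max(b2.r2 - b1.r2, 0.0)  # nested models; clamp float noise
    q = len(block2)
    if q > 0:
        resid_frac = (1 - b2.r2) / fit2.df_resid
        if resid_frac <= 0:  # saturated fit
            delta_f = math.inf if delta_r2 > 0 else np.nan
            delta_p = 0.0 if delta_r2 > 0 else np.nan
        else:
            delta_f = (delta_r2 / q) / resid_frac
            delta_p = float(stats.f.sf(delta_f, q, fit2.df_resid))
    else:
        delta_f, delta_p = np.nan, np.nan

    # semipartial: signed sqrt of unique R^2 contribution in the full model
    semis = {}
    for pred in block1 + block2:
        others = [p for p in block1 + block2 if p != pred]
        r2_without = _ols(y, design(others)).rsquared if others else 0.0
        unique = max(b2.r2 - float(r2_without), 0.0)
        semis[pred] = math.copysign(math.sqrt(unique), fit2.params[pred])

    conf = fit2.conf_int(alpha=1 - ci_level)
    coef = pd.DataFrame(
        {
            "estimate": fit2.params,
            "se": fit2.bse,
            "ci_low": conf[0],
            "ci_high": conf[1],
            "p": fit2.pvalues,
            "semipartial": pd.Series(semis),
        }
    )
    return HierRegressionResult(b1, b2, float(delta_r2), float(delta_f),
                                delta_p, coef)
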