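"""Chained-equations multiple imputation and Rubin's-rules pooling.

The imputer is a fully conditional specification (FCS) sampler: each
incomplete variable is imputed in rotation from a conditional model on
all other variables, cycling a fixed number of iterations per completed
copy.  Continuous variables use Bayesian normal linear regression with
proper posterior parameter draws (sigma^2 from the scaled inverse
chi-square, coefficients from their conditional normal); binary
variables use logistic regression with an asymptotic-normal coefficient
draw.  Observed cells are never altered, and every draw derives from a
caller-supplied seed -- there is no hidden global state.

Downstream estimates from the m completed copies are combined by
Rubin's rules: the pooled estimate is the mean, the total variance is
``W + (1 + 1/m) B`` (within- plus inflated between-imputation variance),
and intervals use Barnard-Rubin degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImputationSet",
    "PooledEstimate",
    "impute",
    "pool",
    "pooled_analysis",
    "fit_ranges",
]


@dataclass(frozen=True)
class ImputationSet:
    """m completed copies of an analysis table plus provenance metadata."""

    tables: tuple[pd.DataFrame, ...]
    seed: int
    iterations: int
    model_registry: Mapping[str, str]   # variable -> "normal" | "logistic"

    @property
    def m(self) -> int:
        return len(self.tables)

    def save(self, directory: str | Path) -> None:
        """Persist as m delimited tables plus a manifest for audit."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, table in enumerate(self.tables, start=1):
            table.to_csv(directory / f"imputation_{i:02d}.csv", index=False)
        manifest = pd.DataFrame(
            {"variable": list(self.model_registry), "model": list(self.model_registry.values())}
        )
        manifest.insert(0, "seed", self.seed)
        manifest.insert(1, "iterations", self.iterations)
        manifest.to_csv(directory / "manifest.csv", index=False)


def _is_binary(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    return len(vals) > 0 and set(np.unique(vals)).issubset({0, 1, 0.0, 1.0, True, False})


def _draw_normal_model(y, X, X_mis, rng):
    """Posterior-predictive draw for a normal linear model (Jeffreys prior)."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - k, 1)
    ss = float(resid @ resid)
    sigma2 = ss / rng.chisquare(df) if ss > 0 else 0.0
    cov = sigma2 * XtX_inv
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    mu = X_mis @ beta
    return mu + rng.normal(0.0, math.sqrt(sigma2), size=len(X_mis))


def _draw_logistic_model(y, X, X_mis, rng):
    """Bernoulli draw from a logistic fit with normal coefficient draw.

    Falls back to the observed empirical rate when the fit is unstable
    (perfect separation, constant outcome).
    """
    import statsmodels.api as sm

    p_obs = float(np.mean(y))
    if p_obs in (0.0, 1.0):
        return rng.binomial(1, p_obs, size=len(X_mis)).astype(float)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            cov = np.asarray(fit.cov_params())
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError
            beta = rng.multivariate_normal(np.asarray(fit.params), cov, method="svd")
    except Exception:
        return rng.binomial(1, p_obs, size=len(X_mis)).astype(float)
    eta = np.clip(X_mis @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    return rng.binomial(1, p).astype(float)


def impute(
    table: pd.DataFrame,
    m: int = 20,
    iterations: int = 10,
    seed: int | None = None,
    variables: Sequence[str] | None = None,
    exclude: Sequence[str] = ("respondent_id",),
) -> ImputationSet:
    """FCS multiple imputation of the numeric columns of ``table``.

    Parameters
    ----------
    table
        The analysis table; NaN marks missing cells.
    m, iterations
        Number of completed copies and FCS cycles per copy.  The default
        m follows the study configuration (20); iterations default to 10
        cycles, ample for the low-dimensional tables imputed here.
    seed
        Required source of randomness; the same seed reproduces the
        ImputationSet bit-for-bit.
    variables
        Columns to include in the imputation model (default: all numeric
        columns except ``exclude``).  Columns with no missing values act
        as predictors only.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if seed is None:
        raise ValueError("a seed is required for imputation")
    if variables is None:
        variables = [
            c for c in table.columns
            if c not in exclude and pd.api.types.is_numeric_dtype(table[c])
        ]
    data = table[list(variables)].astype(float)
    miss = data.isna()
    if miss.all(axis=0).any():
        bad = miss.columns[miss.all(axis=0)].tolist()
        raise ValueError(f"variable(s) with no observed values: {bad}")
    if not (~miss).all(axis=0).any():
        raise ValueError("at least one fully observed variable is required")

    incomplete = [c for c in variables if miss[c].any()]
    registry = {c: ("logistic" if _is_binary(data[c]) else "normal") for c in incomplete}
    rng = np.random.default_rng(seed)

    copies: list[pd.DataFrame] = []
    for _ in range(m):
        work = data.copy()
        # initial fill: random draws from each variable's observed values
        for col in incomplete:
            obs = work[col].dropna().to_numpy()
            work.loc[miss[col], col] = rng.choice(obs, size=int(miss[col].sum()))
        for _ in range(iterations if incomplete else 0):
            for col in incomplete:
                others = [c for c in variables if c != col]
                X_full = np.column_stack(
                    [np.ones(len(work)), work[others].to_numpy(dtype=float)]
                )
                obs_mask = (~miss[col]).to_numpy()
                y_obs = work.loc[obs_mask, col].to_numpy(dtype=float)
                X_obs = X_full[obs_mask]
                X_mis = X_full[~obs_mask]
                if registry[col] == "logistic":
                    draws = _draw_logistic_model(y_obs, X_obs, X_mis, rng)
                else:
                    draws = _draw_normal_model(y_obs, X_obs, X_mis, rng)
                work.loc[~obs_mask, col] = draws
        completed = table.copy()
        completed[list(variables)] = work
        copies.append(completed)

    return ImputationSet(tuple(copies), seed, iterations, registry)


@dataclass(frozen=True)
class PooledEstimate:
    """An estimate combined across imputations by Rubin's rules."""

    estimate: float
    within_variance: float      # W: mean squared SE
    between_variance: float     # B: variance of per-imputation estimates
    total_variance: float       # T = W + (1 + 1/m) B
    se: float
    df: float                   # Barnard-Rubin (or Rubin 1987 when df_com unknown)
    ci: tuple[float, float]
    p: float                    # two-tailed test of estimate == 0
    m: int


def pool(
    estimates: Sequence[float],
    ses: Sequence[float],
    df_com: float | None = None,
    ci_level: float = 0.95,
) -> PooledEstimate:
    """Combine per-imputation (estimate, SE) pairs by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(ses, dtype=float) ** 2
    m = len(q)
    if m < 2 or len(u) != m:
        raise ValueError("need >= 2 matching (estimate, SE) pairs")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t_var = w + (1 + 1 / m) * b
    se = math.sqrt(t_var)

    if b == 0.0 or t_var == 0.0:
        df = math.inf
    else:
        lam = (1 + 1 / m) * b / t_var
        df_old = (m - 1) / lam**2
        if df_com is None:
            df = df_old
        else:
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)

    if se == 0.0:
        ci = (qbar, qbar)
        p = 0.0 if qbar != 0 else 1.0
    else:
        half = stats.t.ppf(0.5 + ci_level / 2, df) * se
        ci = (qbar - half, qbar + half)
        p = float(2 * stats.t.sf(abs(qbar) / se, df))
    return PooledEstimate(qbar, w, b, t_var, se, df, ci, p, m)


def pooled_analysis(
    imp: ImputationSet,
    analysis: Callable[[pd.DataFrame], tuple[float, float] | tuple[float, float, float]],
    ci_level: float = 0.95,
) -> PooledEstimate:
    """Apply an (estimate, SE[, complete-data df]) analysis per copy and pool.

    The analysis callable must be total on each completed table.  When it
    returns a third element it is taken as the complete-data degrees of
    freedom for the Barnard-Rubin adjustment.
    """
    results = [analysis(t) for t in imp.tables]
    ests = [r[0] for r in results]
    ses = [r[1] for r in results]
    df_com = results[0][2] if len(results[0]) > 2 else None
    return pool(ests, ses, df_com=df_com, ci_level=ci_level)


def fit_ranges(
    imp: ImputationSet,
    statistics: Callable[[pd.DataFrame], Mapping[str, float]],
) -> pd.DataFrame:
    """Min-max ranges of non-poolable fit statistics across copies.

    Model-fit quantities like R-squared and F have no Rubin's-rules
    combination; reports give their range over the m imputed datasets
    instead.  Ranges collapse to a point when the data are complete.
    """
    rows = [dict(statistics(t)) for t in imp.tables]
    frame = pd.DataFrame(rows)
    return pd.DataFrame({"min": frame.min(axis=0), "max": frame.max(axis=0)})
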