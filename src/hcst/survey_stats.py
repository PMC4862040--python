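"""Survey-weighted statistics: means with bootstrap-replicate variance and trend tests.

Point estimates are weighted means under the main survey weight.  Standard
errors come from bootstrap replicate weights (balanced-repeated-replication
style): the statistic is recomputed under each replicate-weight column and
the SEM is the root mean squared deviation of the replicate estimates around
the full-sample estimate, optionally Fay-adjusted.

The trend test across compliance quartiles is weighted least squares of the
outcome on the quartile index (1-4 as a linear score) plus covariates (age,
sex, misreporting status) — a deliberate simplification of full
survey-design regression, documented in the methods note.  A weighted
logistic analogue serves binary outcomes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict

__all__ = [
    "WeightedSummary",
    "TrendResult",
    "weighted_mean",
    "weighted_mean_sem",
    "trend_test",
    "logistic_trend",
]


class WeightedSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    mean: float
    sem: Optional[float]
    n_effective: float


class TrendResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    slope: float
    se: float
    p_trend: float
    covariates: tuple[str, ...] = ()


def weighted_mean(values, weights) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return float(np.dot(values, weights) / total)


def weighted_mean_sem(
    values,
    weights,
    replicate_weights=None,
    fay_factor: float = 0.0,
) -> WeightedSummary:
    """Weighted mean with replicate-weight SEM.

    ``replicate_weights`` is an (n, B) array of bootstrap replicate weight
    columns.  SEM = sqrt( 1/(B (1-fay)^2) * sum_b (mean_b - mean)^2 ); with
    no replicates the SEM is missing.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    mean = weighted_mean(values, weights)
    sem: Optional[float] = None
    if replicate_weights is not None:
        rw = np.asarray(replicate_weights, dtype=float)
        if rw.ndim != 2 or rw.shape[0] != values.shape[0]:
            raise ValueError("replicate_weights must be an (n, B) array")
        B = rw.shape[1]
        if B > 0:
            totals = rw.sum(axis=0)
            if np.any(totals <= 0):
                raise ValueError("every replicate-weight column needs positive total weight")
            rep_means = values @ rw / totals
            sem = float(
                np.sqrt(np.mean((rep_means - mean) ** 2)) / (1.0 - fay_factor)
            )
            if sem <= 1e-12 * (abs(mean) + 1.0):  # identical replicates, up to roundoff
                sem = 0.0
    return WeightedSummary(mean=mean, sem=sem, n_effective=float(weights.sum()))


def _design_matrix(
    quartile_index, covariates: Optional[pd.DataFrame]
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    X = pd.DataFrame({"quartile": np.asarray(quartile_index, dtype=float)})
    used: list[str] = []
    if covariates is not None:
        for col in covariates.columns:
            s = covariates[col]
            if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True, dtype=float)
                X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
            else:
                X[col] = np.asarray(s, dtype=float)
            used.append(col)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name a culprit: first column whose removal restores full column rank
        for col in X.columns:
            reduced = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"design matrix is rank-deficient; column {col!r} is collinear")
        raise ValueError("design matrix is rank-deficient")
    return X, tuple(used)


def trend_test(
    outcome,
    quartile_index,
    covariates: Optional[pd.DataFrame] = None,
    weights=None,
) -> TrendResult:
    """Linear trend of an outcome across quartiles, covariate-adjusted.

    Weighted least squares with the quartile index entered as a 1-4 linear
    score; the two-sided p-value is for the quartile slope.
    """
    y = np.asarray(outcome, dtype=float)
    q = np.asarray(quartile_index, dtype=float)
    if not np.all((q >= 1) & (q <= 4)):
        raise ValueError("quartile_index must lie in {1..4}")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    X, used = _design_matrix(q, covariates)
    fit = sm.WLS(y, X, weights=w).fit()
    slope = float(fit.params["quartile"])
    se = float(fit.bse["quartile"])
    p = float(fit.pvalues["quartile"])
    scale = max(1.0, float(np.mean(np.abs(y))))
    if se <= 1e-10 * scale or np.isnan(p):
        # zero residual variance: the trend is exact (or exactly absent)
        exact_zero = abs(slope) <= 1e-10 * scale
        slope = 0.0 if exact_zero else slope
        p = 1.0 if exact_zero else 0.0
    return TrendResult(slope=slope, se=se, p_trend=p, covariates=used)


def logistic_trend(
    outcome,
    quartile_index,
    covariates: Optional[pd.DataFrame] = None,
    weights=None,
) -> dict:
    """Weighted logistic trend for a binary outcome.

    Returns the per-quartile-step odds ratio with a 95 % CI and the Q4-vs-Q1
    odds ratio (three quartile steps), mirroring the reporting shape of
    survey logistic analyses.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    q = np.asarray(quartile_index, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    X, used = _design_matrix(q, covariates)
    fit = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
    beta = float(fit.params["quartile"])
    se = float(fit.bse["quartile"])
    return {
        "or_per_quartile": float(np.exp(beta)),
        "or_ci95": (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        "or_q4_vs_q1": float(np.exp(3 * beta)),
        "p_trend": float(fit.pvalues["quartile"]),
        "covariates": used,
    }
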