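"""Closed-form Haseman-Elston estimators and phenotype preprocessing.

The Haseman-Elston (HE) method-of-moments estimators avoid iterative
likelihood maximization: with W the kinship matrix with zeroed diagonal,

    ĥ²  = yᵀWy / tr(W·W)
    ρ̂k = y1ᵀWy2 / √(y1ᵀWy1 · y2ᵀWy2)

Phenotypes are expected to be mean-zero when these formulas are applied:
real data through the explicit :func:`residualize` step (which at minimum
centers), simulated bootstrap draws by construction.  Centering is *not*
re-applied inside the quadratic forms — projecting out the sample mean a
second time introduces a finite-sample bias of order 1ᵀW1/n² in ĥ², which is
material on cohorts with strong family structure, whereas the estimator is
exactly unbiased on mean-zero data.

ĥ² may fall outside [0, 1] and ρ̂k outside [−1, 1]; ρ̂k is undefined whenever
either quadratic form is nonpositive, which is reported as an explicit
invalid state rather than an exception so bootstrap machinery can tally it.

Preprocessing mirrors common proteomics practice: per-batch rank-normal
transformation, then residualization on covariates (or plain centering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kinship import WeightMatrix

__all__ = [
    "EstimateTriplet",
    "rank_normalize_by_batch",
    "residualize",
    "he_heritability",
    "he_genetic_correlation",
    "estimate_pair",
    "quadratic_forms",
]


@dataclass(frozen=True)
class EstimateTriplet:
    """(ĥ1², ĥ2², ρ̂k) from one pair of phenotypes.

    ``valid`` is False iff ρ̂k is undefined (nonpositive quadratic form), in
    which case ``reason`` says why and ``rho_hat`` is NaN; heritabilities are
    always reported.
    """

    h1_hat: float
    h2_hat: float
    rho_hat: float
    valid: bool = True
    reason: str = ""


def rank_normalize_by_batch(values, batch) -> np.ndarray:
    """Inverse-normal transform values within each batch, keeping sample order.

    Within a batch of m non-missing values, value with (average, tie-sharing)
    rank r maps to Φ⁻¹((r − 0.5)/m).  Missing values (NaN) stay missing and do
    not consume ranks.  Each batch must contribute at least 2 non-missing
    values.
    """
    values = np.asarray(values, dtype=float)
    batch = np.asarray(batch)
    if values.shape != batch.shape:
        raise ValueError("values and batch must have equal length")
    out = np.full_like(values, np.nan)
    for b in pd.unique(batch):
        mask = (batch == b) & ~np.isnan(values)
        m = int(mask.sum())
        if m < 2:
            raise ValueError(
                f"batch {b!r} has {m} non-missing values; need at least 2"
            )
        ranks = pd.Series(values[mask]).rank(method="average").to_numpy()
        out[mask] = norm.ppf((ranks - 0.5) / m)
    return out


def residualize(y, covariates=None) -> np.ndarray:
    """Least-squares residuals of y on an intercept plus optional covariates.

    With ``covariates=None`` this is plain mean-centering.  The covariate
    table (DataFrame or 2-D array) must have full column rank once the
    intercept is added.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None:
        return y - y.mean()
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariate rows must match length of y")
    X = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def quadratic_forms(Y1: np.ndarray, Y2: np.ndarray, W: WeightMatrix):
    """Block-wise (y1ᵀWy1, y2ᵀWy2, y1ᵀWy2) for stacked replicates.

    ``Y1``/``Y2`` are (n_reps, n), assumed preprocessed (mean-zero).
    Exploits W's block structure so the cost is Σ_B n_reps·b_B² instead of
    n_reps·n².
    """
    Y1 = np.atleast_2d(np.asarray(Y1, dtype=float))
    Y2 = np.atleast_2d(np.asarray(Y2, dtype=float))
    n_reps = Y1.shape[0]
    q11 = np.zeros(n_reps)
    q22 = np.zeros(n_reps)
    q12 = np.zeros(n_reps)
    for idx in W.blocks:
        if len(idx) < 2:
            continue
        W_B = W.values[np.ix_(idx, idx)]
        A1 = Y1[:, idx]
        A2 = Y2[:, idx]
        T1 = A1 @ W_B
        q11 += np.einsum("rb,rb->r", T1, A1)
        q12 += np.einsum("rb,rb->r", T1, A2)
        q22 += np.einsum("rb,rb->r", A2 @ W_B, A2)
    return q11, q22, q12


def _check_usable(W: WeightMatrix) -> None:
    if W.trace_ww <= 0:
        raise ValueError(
            "no off-diagonal relatedness: tr(WW) = 0, heritability is not "
            "identifiable from this kinship"
        )


def he_heritability(y, W: WeightMatrix) -> float:
    """HE heritability estimate yᵀWy / tr(WW); y should be residualized first.

    The estimate is unbounded: values below 0 or above 1 are legitimate
    outputs of the moment estimator and are not clipped.
    """
    _check_usable(W)
    y = np.asarray(y, dtype=float)
    q11, _, _ = quadratic_forms(y[None, :], y[None, :], W)
    return float(q11[0] / W.trace_ww)


def he_genetic_correlation(y1, y2, W: WeightMatrix):
    """HE genetic correlation y1ᵀWy2 / √(y1ᵀWy1·y2ᵀWy2), or (nan, reason).

    Returns ``(value, "")`` when defined and ``(nan, reason)`` when either
    denominator quadratic form is ≤ 0.  The value may lie outside [−1, 1].
    """
    _check_usable(W)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    q11, q22, q12 = quadratic_forms(y1[None, :], y2[None, :], W)
    if q11[0] <= 0 or q22[0] <= 0:
        return float("nan"), "nonpositive quadratic form"
    return float(q12[0] / np.sqrt(q11[0] * q22[0])), ""


def estimate_pair(y1, y2, W: WeightMatrix) -> EstimateTriplet:
    """Estimate (ĥ1², ĥ2², ρ̂k) for one phenotype pair."""
    _check_usable(W)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    q11, q22, q12 = quadratic_forms(y1[None, :], y2[None, :], W)
    return _triplet_from_forms(q11[0], q22[0], q12[0], W.trace_ww)


def _triplet_from_forms(q11, q22, q12, trace_ww) -> EstimateTriplet:
    h1 = q11 / trace_ww
    h2 = q22 / trace_ww
    if q11 <= 0 or q22 <= 0:
        return EstimateTriplet(
            h1_hat=float(h1),
            h2_hat=float(h2),
            rho_hat=float("nan"),
            valid=False,
            reason="nonpositive quadratic form",
        )
    return EstimateTriplet(
        h1_hat=float(h1),
        h2_hat=float(h2),
        rho_hat=float(q12 / np.sqrt(q11 * q22)),
    )


def estimate_pairs_batch(Y1: np.ndarray, Y2: np.ndarray, W: WeightMatrix):
    """Vectorized estimation over stacked replicates.

    Returns (h1_hat, h2_hat, rho_hat, valid) arrays of length n_reps; invalid
    replicates have NaN rho_hat.  This is the hot path of the parametric
    bootstrap.
    """
    _check_usable(W)
    q11, q22, q12 = quadratic_forms(Y1, Y2, W)
    h1 = q11 / W.trace_ww
    h2 = q22 / W.trace_ww
    valid = (q11 > 0) & (q22 > 0)
    rho = np.full_like(q11, np.nan)
    rho[valid] = q12[valid] / np.sqrt(q11[valid] * q22[valid])
    return h1, h2, rho, valid
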