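"""Confidence intervals and p-values for the genetic correlation.

Three interval constructions are provided:

``pmf``
    Percentiles of the bootstrap conditional PMF.  The discrete mass is
    treated as uniform within each bin, giving a piecewise-linear CDF, and
    bounds are placed by linear interpolation.  Because the parameter is
    bounded, mass can pile up against ±1 and an equal-tail interval may be
    infeasible; three cases are distinguished by the cumulative probability
    ``cpl`` at the estimate: too little mass below it (Case 1: the interval
    starts at the support's lower end), too little above (Case 2: it ends at
    the support's upper end), or both tails feasible (Case 3: the ordinary
    equal-tail interval).  In every case the interval carries mass ≥ 1−α.

``beta``
    A continuous beta approximation to the PMF: bin midpoints are mapped from
    [−1, 1] to [0, 1], beta shapes fit by moment matching, equal-tail beta
    quantiles taken, and the bounds mapped back.  Being continuous, it
    supports arbitrarily small α and hence small p-values.

``fisher``
    The classical comparator: treat ρ̂k like a Pearson correlation, apply
    Fisher's z = arctanh(ρ̂) with standard deviation 1/√(Neff − 3), where the
    effective sample size Neff = tr(W·W), and back-transform the normal
    interval with tanh.

p-values come from interval inversion: p is the smallest α at which the
level-(1−α) interval excludes 0, located by bisection to a configurable
sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .pmf import ConditionalPMF

__all__ = [
    "ConfidenceInterval",
    "BetaFit",
    "pmf_cdf",
    "ci_pmf",
    "fit_beta",
    "ci_beta",
    "ci_fisher",
    "pvalue_inversion",
    "bh_fdr",
]


@dataclass(frozen=True)
class ConfidenceInterval:
    """A (lower, upper) interval for ρk at confidence level 1−α."""

    lower: float
    upper: float
    level: float
    method: str
    case: str = "n/a"

    def __post_init__(self):
        if not -1.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(
                f"invalid interval [{self.lower}, {self.upper}] for method "
                f"{self.method}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class BetaFit:
    """Moment-matched beta shapes on the [0, 1] transformed correlation scale."""

    a: float
    b: float

    def __post_init__(self):
        if not (np.isfinite(self.a) and np.isfinite(self.b) and self.a > 0 and self.b > 0):
            raise ValueError(f"beta shapes must be finite and positive, got {self.a}, {self.b}")


def _cumulative(pmf: ConditionalPMF):
    edges = pmf.scheme.rho_edges
    cum = np.concatenate([[0.0], np.cumsum(pmf.probs)])
    cum[-1] = 1.0  # guard against accumulated rounding
    return edges, cum


def pmf_cdf(pmf: ConditionalPMF, x: float) -> float:
    """Piecewise-linear CDF of the conditional PMF at x ∈ [−1, 1]."""
    if not -1.0 <= x <= 1.0:
        raise ValueError(f"x must be in [-1, 1], got {x}")
    edges, cum = _cumulative(pmf)
    return float(np.interp(x, edges, cum))


def _quantile_upper(edges, cum, q):
    """Smallest x with CDF(x) >= q (left end of any flat stretch)."""
    i = int(np.searchsorted(cum, q, side="left"))
    if i == 0:
        return float(edges[0])
    i = min(i, len(cum) - 1)
    mass = cum[i] - cum[i - 1]
    frac = (q - cum[i - 1]) / mass
    return float(edges[i - 1] + frac * (edges[i] - edges[i - 1]))


def _quantile_lower(edges, cum, q):
    """Largest x with CDF(x) <= q (right end of any flat stretch)."""
    i = int(np.searchsorted(cum, q, side="right")) - 1
    if i >= len(cum) - 1:
        return float(edges[-1])
    mass = cum[i + 1] - cum[i]
    frac = (q - cum[i]) / mass
    return float(edges[i] + frac * (edges[i + 1] - edges[i]))


def _support_bounds(pmf: ConditionalPMF):
    pos = np.nonzero(pmf.probs > 0)[0]
    edges = pmf.scheme.rho_edges
    return float(edges[pos[0]]), float(edges[pos[-1] + 1])


def ci_pmf(pmf: ConditionalPMF, rho_hat: float, alpha: float) -> ConfidenceInterval:
    """Level-(1−α) interval from the discrete PMF (Cases 1-3, interpolated).

    ``rho_hat`` only determines the case through cpl = CDF(ρ̂); estimates
    overshooting [−1, 1] are clamped for that evaluation.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    edges, cum = _cumulative(pmf)
    cpl = float(np.interp(np.clip(rho_hat, -1.0, 1.0), edges, cum))
    support_lo, support_hi = _support_bounds(pmf)
    half = alpha / 2.0
    if cpl < half:
        # too little mass below the estimate for an equal lower tail
        lower = support_lo
        upper = _quantile_upper(edges, cum, (1.0 - alpha) + float(np.interp(lower, edges, cum)))
        case = "1"
    elif 1.0 - cpl < half:
        upper = support_hi
        lower = _quantile_lower(edges, cum, float(np.interp(upper, edges, cum)) - (1.0 - alpha))
        case = "2"
    else:
        lower = _quantile_lower(edges, cum, half)
        upper = _quantile_upper(edges, cum, 1.0 - half)
        case = "3"
    return ConfidenceInterval(
        lower=lower, upper=upper, level=1.0 - alpha, method="pmf", case=case
    )


def fit_beta(pmf: ConditionalPMF) -> BetaFit:
    """Moment-matched beta approximation on the transformed [0, 1] scale.

    Bin midpoints m are mapped to (m+1)/2; the PMF mean μ and variance v on
    that scale give shapes a = μ·(μ(1−μ)/v − 1), b = (1−μ)·(μ(1−μ)/v − 1).
    Requires at least two bins with positive mass and v < μ(1−μ).
    """
    if pmf.support_count < 2:
        raise ValueError("degenerate PMF, use pmf method")
    m = (pmf.scheme.rho_midpoints() + 1.0) / 2.0
    mu = float(np.sum(pmf.probs * m))
    v = float(np.sum(pmf.probs * (m - mu) ** 2))
    if v <= 0 or v >= mu * (1.0 - mu):
        raise ValueError(
            f"beta moment fit infeasible: variance {v:.4g} vs bound "
            f"{mu * (1 - mu):.4g}"
        )
    nu = mu * (1.0 - mu) / v - 1.0
    return BetaFit(a=mu * nu, b=(1.0 - mu) * nu)


def ci_beta(fit: BetaFit, alpha: float) -> ConfidenceInterval:
    """Equal-tail beta interval, mapped back from [0, 1] to [−1, 1]."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lo = 2.0 * float(beta_dist.ppf(alpha / 2.0, fit.a, fit.b)) - 1.0
    hi = 2.0 * float(beta_dist.ppf(1.0 - alpha / 2.0, fit.a, fit.b)) - 1.0
    return ConfidenceInterval(lower=lo, upper=hi, level=1.0 - alpha, method="beta")


def ci_fisher(rho_hat: float, n_eff: float, alpha: float) -> ConfidenceInterval:
    """Fisher-transformation interval with effective sample size Neff = tr(WW)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_eff <= 3:
        raise ValueError(f"n_eff must exceed 3, got {n_eff}")
    if abs(rho_hat) >= 1.0:
        raise ValueError("transform undefined at boundary |rho_hat| >= 1")
    z = np.arctanh(rho_hat)
    sigma = 1.0 / np.sqrt(n_eff - 3.0)
    zq = norm.ppf(1.0 - alpha / 2.0)
    return ConfidenceInterval(
        lower=float(np.tanh(z - zq * sigma)),
        upper=float(np.tanh(z + zq * sigma)),
        level=1.0 - alpha,
        method="fisher",
    )


def pvalue_inversion(
    pmf: ConditionalPMF,
    method: str = "beta",
    sensitivity: float = 1e-6,
    rho_hat: float | None = None,
) -> float:
    """p-value for H0: ρk = 0 by interval inversion with bisection on α.

    Returns the smallest α (to within ``sensitivity``) at which the 1−α
    interval excludes 0; values below the sensitivity floor are reported as
    the floor itself (read as "p ≤ sensitivity").  The beta method is the
    default because its continuous quantiles resolve arbitrarily small
    p-values; the pmf method uses the discrete-PMF interval and needs
    ``rho_hat`` for its case decision (defaults to the PMF mean).
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    if method == "beta":
        fit = fit_beta(pmf)

        def excludes_zero(a: float) -> bool:
            ci = ci_beta(fit, a)
            return ci.lower > 0.0 or ci.upper < 0.0

    elif method == "pmf":
        if rho_hat is None:
            rho_hat = float(np.sum(pmf.probs * pmf.scheme.rho_midpoints()))

        def excludes_zero(a: float) -> bool:
            ci = ci_pmf(pmf, rho_hat, a)
            return ci.lower > 0.0 or ci.upper < 0.0

    else:
        raise ValueError(f"method must be 'beta' or 'pmf', got {method!r}")

    lo = sensitivity
    hi = 1.0 - min(sensitivity, 1e-9)
    if excludes_zero(lo):
        return lo
    if not excludes_zero(hi):
        return 1.0
    # invariant: CI at lo covers 0, CI at hi excludes it; intervals shrink
    # with alpha so the crossing is unique
    for _ in range(200):
        if hi - lo <= sensitivity:
            break
        mid = (lo + hi) / 2.0
        if excludes_zero(mid):
            hi = mid
        else:
            lo = mid
    return hi


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
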