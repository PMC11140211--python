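"""Discretization bins and the conditional PMF of the true genetic correlation.

The bootstrap works on a discretized parameter space: heritabilities live in
10 bins of width 0.1 on [0, 1] and genetic correlations in 20 bins of width
0.1 on [−1, 1].  All bins are half-open [a, b) except the last on each axis,
which is closed so that the upper boundary (h² = 1, ρ = 1) is covered — e.g.
ρ = 0.9 falls in the final bin [0.9, 1], not in [0.8, 0.9).

Given a bootstrap count store and an observed estimate triplet
(ĥ1², ĥ2², ρ̂k), Bayes' theorem with a uniform prior over the simulation grid
gives the conditional PMF of the true correlation bin:

    Pr(ρ̃ ∈ A_r | obs) ∝ Σ_{h̃1, h̃2}  p̂(obs | h̃1, h̃2, ρ̃_r)

where p̂(obs | combo) is the fraction of that combination's valid bootstrap
replicates whose estimate triplet landed in the observed bins.  The uniform
prior factors 1/(nρ·nh²) cancel in the normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BinScheme", "ConditionalPMF", "bin_index", "conditional_pmf"]


@dataclass(frozen=True)
class BinScheme:
    """Bin edges for the heritability and correlation axes (width 0.1)."""

    h_edges: np.ndarray = None
    rho_edges: np.ndarray = None

    def __post_init__(self):
        # exact decimal edges: naive linspace floats would misplace e.g. 0.9
        h = (
            self.h_edges
            if self.h_edges is not None
            else np.round(np.linspace(0.0, 1.0, 11), 10)
        )
        r = (
            self.rho_edges
            if self.rho_edges is not None
            else np.round(np.linspace(-1.0, 1.0, 21), 10)
        )
        h = np.asarray(h, dtype=float)
        r = np.asarray(r, dtype=float)
        for name, e in (("h_edges", h), ("rho_edges", r)):
            if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
                raise ValueError(f"{name} must be strictly increasing 1-D edges")
        h.flags.writeable = False
        r.flags.writeable = False
        object.__setattr__(self, "h_edges", h)
        object.__setattr__(self, "rho_edges", r)

    @property
    def n_h(self) -> int:
        return len(self.h_edges) - 1

    @property
    def n_rho(self) -> int:
        return len(self.rho_edges) - 1

    def h_midpoints(self) -> np.ndarray:
        return (self.h_edges[:-1] + self.h_edges[1:]) / 2.0

    def rho_midpoints(self) -> np.ndarray:
        return (self.rho_edges[:-1] + self.rho_edges[1:]) / 2.0

    def __eq__(self, other):
        return (
            isinstance(other, BinScheme)
            and np.array_equal(self.h_edges, other.h_edges)
            and np.array_equal(self.rho_edges, other.rho_edges)
        )


def bin_index(value, axis: str, scheme: BinScheme | None = None):
    """Zero-based bin of ``value`` on the ``h`` or ``rho`` axis.

    Bins are half-open with a closed last bin; values outside the support
    (HE estimates may overshoot) clamp to the first/last bin.  Accepts
    scalars or arrays; non-finite values raise.
    """
    scheme = scheme or BinScheme()
    if axis == "h":
        edges = scheme.h_edges
    elif axis == "rho":
        edges = scheme.rho_edges
    else:
        raise ValueError(f"axis must be 'h' or 'rho', got {axis!r}")
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot bin non-finite values")
    idx = np.searchsorted(edges, arr, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    if arr.ndim == 0:
        return int(idx)
    return idx.astype(np.intp)


@dataclass(frozen=True)
class ConditionalPMF:
    """Probability mass of the true genetic-correlation bin given an estimate.

    ``probs`` has one entry per ρ bin of ``scheme`` (20 by default), sums to 1
    and is nonnegative; ``observed`` records the (ĥ1-bin, ĥ2-bin, ρ̂-bin)
    triplet conditioned on.
    """

    probs: np.ndarray
    observed: tuple
    scheme: BinScheme = None

    def __post_init__(self):
        scheme = self.scheme or BinScheme()
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (scheme.n_rho,):
            raise ValueError(
                f"probs must have {scheme.n_rho} entries, got shape {p.shape}"
            )
        if np.any(p < 0):
            raise ValueError("probs must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probs must sum to 1, got {p.sum()!r}")
        p.flags.writeable = False
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "scheme", scheme)

    @property
    def support_count(self) -> int:
        return int(np.count_nonzero(self.probs))


class UnsupportedEstimateRegionError(ValueError):
    """The observed estimate bins were never realized anywhere in the store."""


def conditional_pmf(store, estimates, laplace: float = 0.0) -> ConditionalPMF:
    """Bayes-derived PMF of the true ρ bin given an observed estimate triplet.

    Parameters
    ----------
    store : BootstrapStore
        Binned bootstrap counts over the simulation grid.
    estimates : EstimateTriplet
        Must be valid (finite ρ̂); its values are binned with clamping.
    laplace : float
        Optional additive smoothing count per cell (default 0 = off).  With
        smoothing off, an observed triplet with zero probability under every
        grid combination raises :class:`UnsupportedEstimateRegionError`
        rather than silently inventing mass.

    For each grid ρ̃ value the per-(h̃1, h̃2) conditional probabilities of the
    observed bins are averaged (uniform prior over the grid, which cancels in
    normalization except through combinations excluded for having zero valid
    replicates).
    """
    if not estimates.valid:
        raise ValueError(f"cannot condition on invalid estimate: {estimates.reason}")
    scheme = store.scheme
    i = bin_index(estimates.h1_hat, "h", scheme)
    j = bin_index(estimates.h2_hat, "h", scheme)
    k = bin_index(estimates.rho_hat, "rho", scheme)

    # counts[h1g, h2g, rg] at the observed estimate bins; valid_reps same shape
    obs_counts = store.counts[:, :, :, i, j, k].astype(float) + laplace
    denom = store.valid_reps.astype(float)
    if laplace > 0:
        denom = denom + laplace * (scheme.n_h**2 * scheme.n_rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        phat = np.where(denom > 0, obs_counts / np.where(denom > 0, denom, 1.0), 0.0)
    per_rho_value = phat.sum(axis=(0, 1))  # one entry per grid rho value

    probs = np.zeros(scheme.n_rho)
    rho_bins = bin_index(np.asarray(store.grid.rho_values), "rho", scheme)
    np.add.at(probs, rho_bins, per_rho_value)
    total = probs.sum()
    if total <= 0:
        raise UnsupportedEstimateRegionError(
            f"estimate bins (h1={i}, h2={j}, rho={k}) were never realized in "
            "the bootstrap store; increase n_reps or coarsen bins"
        )
    return ConditionalPMF(probs=probs / total, observed=(i, j, k), scheme=scheme)
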