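"""Sampling paired phenotypes from the bivariate kinship-structured model.

For a pair of traits with heritabilities ``h1², h2²``, genetic correlation
``ρk`` and residual (environmental) correlation ``ρe``, and total variance of
each trait normalized to 1, the joint distribution of the two length-``n``
phenotype vectors is mean-zero multivariate normal with

    var(y1)      = h1²·K + (1−h1²)·I
    var(y2)      = h2²·K + (1−h2²)·I
    cov(y1, y2)  = h1·h2·ρk·K + √(1−h1²)·√(1−h2²)·ρe·I

Because K is block diagonal, the 2n×2n joint covariance decomposes into
independent 2b×2b problems, one per kinship block of size b, and sampling is
done block by block through an eigendecomposition (robust to the singular
covariances that arise at boundary parameters h² = 1 or |ρ| = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinship import KinshipMatrix

__all__ = ["TraitPairParams", "PhenotypePairDraws", "pair_covariance_blocks", "draw_pairs"]

#: eigenvalues of a block covariance below -PSD_TOL are an error;
#: in (-PSD_TOL, 0) they are clipped to 0 before factorization
PSD_TOL = 1e-8

#: replicates are sampled in chunks of this many draws, each chunk with its
#: own seeded stream, so results do not depend on how work is parallelized
CHUNK_SIZE = 1000


@dataclass(frozen=True)
class TraitPairParams:
    """Generative parameters for one pair of traits (total variance = 1)."""

    h1_sq: float
    h2_sq: float
    rho_k: float
    rho_e: float

    def __post_init__(self):
        if not 0.0 <= self.h1_sq <= 1.0:
            raise ValueError(f"h1_sq must be in [0, 1], got {self.h1_sq}")
        if not 0.0 <= self.h2_sq <= 1.0:
            raise ValueError(f"h2_sq must be in [0, 1], got {self.h2_sq}")
        if not -1.0 <= self.rho_k <= 1.0:
            raise ValueError(f"rho_k must be in [-1, 1], got {self.rho_k}")
        if not -1.0 <= self.rho_e <= 1.0:
            raise ValueError(f"rho_e must be in [-1, 1], got {self.rho_e}")


@dataclass(frozen=True)
class PhenotypePairDraws:
    """``n_reps`` sampled pairs of phenotype vectors.

    ``y1`` and ``y2`` are (n_reps, n) arrays; row r is replicate r.
    Reproducible from (kinship, params, n_reps, seed).
    """

    params: TraitPairParams
    n_reps: int
    y1: np.ndarray
    y2: np.ndarray
    seed: int


def pair_covariance_blocks(K: KinshipMatrix, params: TraitPairParams) -> list:
    """Per-block 2b×2b joint covariance matrices of (y1_B, y2_B).

    Raises if any kinship block is not positive semi-definite (smallest
    eigenvalue below −1e-8), naming the offending block.
    """
    covs = []
    for bi, idx in enumerate(K.blocks):
        K_B = K.values[np.ix_(idx, idx)]
        if len(idx) > 1:
            w = np.linalg.eigvalsh(K_B)
            if w[0] < -PSD_TOL:
                raise ValueError(
                    f"kinship block {bi} (first sample {K.ids[idx[0]]}) is not "
                    f"positive semi-definite: min eigenvalue {w[0]:.3g}"
                )
        covs.append(_block_cov(K_B, params))
    return covs


def _block_cov(K_B: np.ndarray, p: TraitPairParams) -> np.ndarray:
    b = K_B.shape[0]
    I = np.eye(b)
    h1, h2 = np.sqrt(p.h1_sq), np.sqrt(p.h2_sq)
    e1, e2 = np.sqrt(1.0 - p.h1_sq), np.sqrt(1.0 - p.h2_sq)
    v1 = p.h1_sq * K_B + (1.0 - p.h1_sq) * I
    v2 = p.h2_sq * K_B + (1.0 - p.h2_sq) * I
    c12 = h1 * h2 * p.rho_k * K_B + e1 * e2 * p.rho_e * I
    top = np.hstack([v1, c12])
    bot = np.hstack([c12.T, v2])
    return np.vstack([top, bot])


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric factor L with L·Lᵀ = cov, tolerating singular covariances."""
    w, V = np.linalg.eigh(cov)
    if w[0] < -PSD_TOL:
        raise ValueError(
            f"block covariance not positive semi-definite: min eigenvalue {w[0]:.3g}"
        )
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def draw_pairs(
    K: KinshipMatrix,
    params: TraitPairParams,
    n_reps: int,
    seed: int,
) -> PhenotypePairDraws:
    """Draw ``n_reps`` independent phenotype pairs under the bivariate model.

    Sampling is independent per kinship block with one seeded stream per
    (block, replicate-chunk); the output is therefore bitwise reproducible
    for fixed inputs regardless of any outer parallelism.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = K.n
    y1 = np.empty((n_reps, n))
    y2 = np.empty((n_reps, n))
    covs = pair_covariance_blocks(K, params)
    chunk_bounds = list(range(0, n_reps, CHUNK_SIZE)) + [n_reps]
    for bi, idx in enumerate(K.blocks):
        b = len(idx)
        L = _psd_factor(covs[bi])
        for ci in range(len(chunk_bounds) - 1):
            lo, hi = chunk_bounds[ci], chunk_bounds[ci + 1]
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence((seed, bi, ci)))
            )
            z = rng.standard_normal((hi - lo, 2 * b))
            draws = z @ L.T
            y1[lo:hi, idx] = draws[:, :b]
            y2[lo:hi, idx] = draws[:, b:]
    return PhenotypePairDraws(params=params, n_reps=n_reps, y1=y1, y2=y2, seed=seed)
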