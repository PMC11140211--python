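"""Kinship (genetic relationship) matrices: I/O, validation, block structure.

A kinship matrix ``K`` encodes pairwise genetic relatedness between the ``n``
individuals of a study; under the linear mixed model used throughout this
package, the phenotypic covariance of a trait with heritability ``h²`` is
``h²·K + (1−h²)·I`` (total variance normalized to 1).  Most real matrices are
sparsified so that individuals in different families ("blocks") have exactly
zero relatedness, and every expensive computation in this package runs block
by block.

Two on-disk dialects are supported: a dense tab-delimited text matrix with
sample IDs (canonical, written and read), and the GCTA GRM binary
lower-triangle pair (read-only).
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "KinshipMatrix",
    "WeightMatrix",
    "load_kinship",
    "save_kinship",
    "zero_diagonal_weight",
    "detect_blocks",
    "effective_sample_size",
    "make_synthetic_kinship",
    "replicate_blocks",
]

#: absolute tolerance for declaring K symmetric
SYMMETRY_TOL = 1e-8


class KinshipValidationError(ValueError):
    """Raised when a matrix fails kinship validation (asymmetry, bad IDs...)."""


@dataclass(frozen=True)
class KinshipMatrix:
    """A validated symmetric relatedness matrix with sample IDs and blocks.

    Attributes
    ----------
    ids : tuple of str
        Sample identifiers, in matrix row/column order.
    values : ndarray, shape (n, n)
        Symmetric relationship coefficients.  Symmetrized exactly as
        ``(K + Kᵀ)/2`` at construction so quadratic forms downstream see an
        exactly symmetric matrix.
    blocks : tuple of ndarray
        Connected components of the nonzero-relatedness graph, each an array
        of row indices.  Individuals in distinct blocks have relatedness 0.
    """

    ids: tuple
    values: np.ndarray
    blocks: tuple = field(default=None)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise KinshipValidationError(
                f"kinship matrix must be square, got shape {vals.shape}"
            )
        n = vals.shape[0]
        ids = tuple(str(i) for i in self.ids)
        if len(ids) != n:
            raise KinshipValidationError(
                f"{len(ids)} sample IDs for a {n}x{n} matrix"
            )
        if len(set(ids)) != n:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise KinshipValidationError(f"duplicate sample IDs: {dupes[:5]}")
        asym = np.abs(vals - vals.T)
        worst = np.unravel_index(np.argmax(asym), asym.shape)
        if asym[worst] > SYMMETRY_TOL:
            raise KinshipValidationError(
                "matrix not symmetric: worst entry "
                f"({ids[worst[0]]}, {ids[worst[1]]}) differs by {asym[worst]:.3g}"
            )
        vals = (vals + vals.T) / 2.0
        vals.flags.writeable = False
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", vals)
        if self.blocks is None:
            object.__setattr__(self, "blocks", detect_blocks(vals))
        else:
            object.__setattr__(
                self, "blocks", tuple(np.asarray(b, dtype=np.intp) for b in self.blocks)
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def checksum(self) -> str:
        """SHA-256 over IDs and values rounded to 10 decimals (for provenance)."""
        h = hashlib.sha256()
        h.update("\x00".join(self.ids).encode())
        h.update(np.round(self.values, 10).tobytes())
        return h.hexdigest()

    def block_sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.blocks])


@dataclass(frozen=True)
class WeightMatrix:
    """Weight matrix for Haseman-Elston quadratic forms.

    The kinship matrix with its diagonal zeroed; ``trace_ww = tr(W·W)`` is the
    effective sample size used by the Fisher-transformation interval, and the
    denominator of the heritability estimator.  ``blocks`` mirrors the
    originating kinship's block partition so quadratic forms can be evaluated
    block-wise.
    """

    values: np.ndarray
    trace_ww: float
    blocks: tuple = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if np.any(np.diagonal(vals) != 0.0):
            raise ValueError("weight matrix diagonal must be exactly zero")
        object.__setattr__(self, "values", vals)
        if self.blocks is None:
            object.__setattr__(self, "blocks", detect_blocks(vals))

    @property
    def n(self) -> int:
        return self.values.shape[0]


def detect_blocks(values: np.ndarray, tol: float = 0.0) -> tuple:
    """Partition indices into connected components of the relatedness graph.

    Two individuals i ≠ j are connected iff ``|values[i, j]| > tol``.  Returns
    a tuple of sorted index arrays, ordered by their smallest member.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    vals = np.asarray(values, dtype=float)
    off = vals.copy()
    np.fill_diagonal(off, 0.0)
    adj = csr_matrix(np.abs(off) > tol)
    n_comp, labels = connected_components(adj, directed=False)
    members = [[] for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        members[lab].append(idx)
    blocks = [np.asarray(m, dtype=np.intp) for m in members]
    blocks.sort(key=lambda b: b[0])
    return tuple(blocks)


def zero_diagonal_weight(K: KinshipMatrix) -> WeightMatrix:
    """Return W = K with diagonal set to zero, plus tr(W·W).

    tr(W·W) equals the sum of squared off-diagonal entries of K because W is
    symmetric; it is 0 for an identity kinship (no relatedness to exploit),
    which downstream estimators reject.
    """
    W = K.values.copy()
    np.fill_diagonal(W, 0.0)
    trace_ww = float(np.sum(W * W))
    return WeightMatrix(values=W, trace_ww=trace_ww, blocks=K.blocks)


def effective_sample_size(K: KinshipMatrix) -> float:
    """Effective sample size Neff = tr(W·W) with W the zero-diagonal kinship.

    A relatedness-weighted analogue of sample size; additive over blocks and
    invariant under simultaneous row/column permutation.
    """
    return zero_diagonal_weight(K).trace_ww


def make_synthetic_kinship(
    n_families: int,
    family_size: int,
    within_coefficient: float = 0.5,
    n_singletons: int = 0,
    seed: int = 0,
) -> KinshipMatrix:
    """Block-diagonal kinship of equicorrelated families plus singletons.

    Each of the ``n_families`` families is a ``family_size``-square block with
    1 on the diagonal and ``within_coefficient`` off it; singletons contribute
    1×1 blocks.  Deterministic given its arguments (``seed`` is accepted for
    interface uniformity and reserved for future randomized variants).
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if not 0.0 <= within_coefficient < 1.0:
        raise ValueError("within_coefficient must be in [0, 1)")
    n = n_families * family_size + n_singletons
    values = np.eye(n)
    fam = np.full((family_size, family_size), within_coefficient)
    np.fill_diagonal(fam, 1.0)
    for f in range(n_families):
        s = f * family_size
        values[s : s + family_size, s : s + family_size] = fam
    ids = [f"fam{f + 1}_{m + 1}" for f in range(n_families) for m in range(family_size)]
    ids += [f"single{s + 1}" for s in range(n_singletons)]
    return KinshipMatrix(ids=tuple(ids), values=values)


def replicate_blocks(K: KinshipMatrix, times: int) -> KinshipMatrix:
    """Block-diagonal replication of K, emulating a larger cohort.

    The result has ``times`` unrelated copies of the input cohort; sample IDs
    get a per-copy suffix so they stay unique.  Used to study how interval
    methods behave as the effective sample size grows.
    """
    if times < 1:
        raise ValueError("times must be >= 1")
    if times == 1:
        return K
    n = K.n
    values = np.zeros((n * times, n * times))
    ids = []
    blocks = []
    for c in range(times):
        values[c * n : (c + 1) * n, c * n : (c + 1) * n] = K.values
        ids.extend(f"{i}_rep{c + 1}" for i in K.ids)
        blocks.extend(b + c * n for b in K.blocks)
    return KinshipMatrix(ids=tuple(ids), values=values, blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# I/O


def save_kinship(K: KinshipMatrix, path) -> None:
    """Write the dense tab-delimited dialect: ID header row, then ID + n values."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(K.ids) + "\n")
        for i, row in enumerate(K.values):
            fh.write(K.ids[i] + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_kinship(path, format: str = "dense-tsv") -> KinshipMatrix:
    """Read a kinship matrix.

    Parameters
    ----------
    path : str or Path
        For ``dense-tsv``: the matrix file.  For ``grm``: the GCTA prefix
        (``PREFIX.grm.bin`` + ``PREFIX.grm.id``) or the ``.grm.bin`` path.
    format : {"dense-tsv", "grm"}

    Validation (symmetry, unique IDs, squareness) happens at construction;
    block structure is computed from exact zeros.
    """
    if format == "dense-tsv":
        return _load_dense_tsv(path)
    if format == "grm":
        return _load_grm(path)
    raise ValueError(f"unknown kinship format: {format!r}")


def _load_dense_tsv(path) -> KinshipMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids = [h for h in header if h != ""]
        rows = []
        row_ids = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            row_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    n = len(ids)
    values = np.asarray(rows, dtype=float)
    if values.shape != (n, n):
        raise KinshipValidationError(
            f"non-square dense-tsv matrix: {len(ids)} header IDs, "
            f"value block of shape {values.shape}"
        )
    if row_ids != ids:
        raise KinshipValidationError("row IDs do not match header IDs")
    return KinshipMatrix(ids=tuple(ids), values=values)


def _load_grm(path) -> KinshipMatrix:
    """GCTA GRM dialect: float32 lower triangle (diagonal included), row-major."""
    path = str(path)
    if path.endswith(".grm.bin"):
        path = path[: -len(".grm.bin")]
    id_path = Path(path + ".grm.id")
    bin_path = Path(path + ".grm.bin")
    ids = []
    with id_path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            # FID + IID columns; join so IDs stay unique across families
            ids.append("_".join(parts[:2]) if len(parts) > 1 else parts[0])
    n = len(ids)
    n_entries = n * (n + 1) // 2
    raw = bin_path.read_bytes()
    if len(raw) != 4 * n_entries:
        raise KinshipValidationError(
            f"GRM binary has {len(raw)} bytes, expected {4 * n_entries} "
            f"for {n} samples"
        )
    tri = np.array(struct.unpack(f"<{n_entries}f", raw), dtype=float)
    values = np.zeros((n, n))
    k = 0
    for i in range(n):
        values[i, : i + 1] = tri[k : k + i + 1]
        k += i + 1
    values = values + np.tril(values, -1).T
    return KinshipMatrix(ids=tuple(ids), values=values)
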