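"""The parametric bootstrap grid and its persisted count store.

The bootstrap simulates phenotype pairs for every combination of candidate
heritabilities (h̃1², h̃2²) and genetic correlation ρ̃k on a grid of bin
midpoints — by default 10 × 10 × 20 = 2,000 combinations with 0.1 spacing:

    h̃²  ∈ {0.05, 0.15, ..., 0.95}
    ρ̃k ∈ {−0.95, −0.85, ..., −0.05, 0.05, ..., 0.95}

For each combination, ``n_reps`` pairs are drawn, Haseman-Elston triplets
(ĥ1², ĥ2², ρ̂k) estimated, and the triplets binned.  Only the resulting
integer count tensor is persisted: the conditional PMF needs nothing else,
storage stays small, and stores from disjoint seeds can simply be added.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from . import __version__ as _pkg_version
from .estimators import estimate_pairs_batch
from .kinship import KinshipMatrix, zero_diagonal_weight
from .pmf import BinScheme, bin_index
from .simulate import TraitPairParams, draw_pairs

__all__ = [
    "GridSpec",
    "BootstrapStore",
    "default_grid",
    "run_grid",
    "save_store",
    "load_store",
    "merge_stores",
    "export_long_table",
]


@dataclass(frozen=True)
class GridSpec:
    """Simulation grid: candidate parameter values plus bootstrap settings.

    Every grid value must sit at the midpoint of exactly one bin of the bin
    scheme (validated at construction) so each combination maps to a unique
    true-parameter bin triple.
    """

    h1_values: tuple
    h2_values: tuple
    rho_values: tuple
    rho_e: float
    n_reps: int
    seed: int
    scheme: BinScheme = field(default_factory=BinScheme)

    def __post_init__(self):
        h1 = tuple(float(v) for v in self.h1_values)
        h2 = tuple(float(v) for v in self.h2_values)
        rho = tuple(float(v) for v in self.rho_values)
        for name, vals in (("h1_values", h1), ("h2_values", h2), ("rho_values", rho)):
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        for vals, axis, mids in (
            (h1, "h", self.scheme.h_midpoints()),
            (h2, "h", self.scheme.h_midpoints()),
            (rho, "rho", self.scheme.rho_midpoints()),
        ):
            for v in vals:
                b = bin_index(v, axis, self.scheme)
                if abs(v - mids[b]) > 1e-9:
                    raise ValueError(
                        f"grid value {v} is not the midpoint of its {axis} bin "
                        f"(expected {mids[b]})"
                    )
        if not -1.0 <= self.rho_e <= 1.0:
            raise ValueError("rho_e must be in [-1, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        object.__setattr__(self, "h1_values", h1)
        object.__setattr__(self, "h2_values", h2)
        object.__setattr__(self, "rho_values", rho)

    @property
    def n_combinations(self) -> int:
        return len(self.h1_values) * len(self.h2_values) * len(self.rho_values)

    @property
    def shape(self) -> tuple:
        return (len(self.h1_values), len(self.h2_values), len(self.rho_values))

    def combinations(self):
        """Yield (flat_index, (i, j, k), TraitPairParams) in C order."""
        flat = 0
        for i, h1 in enumerate(self.h1_values):
            for j, h2 in enumerate(self.h2_values):
                for k, rho in enumerate(self.rho_values):
                    yield flat, (i, j, k), TraitPairParams(
                        h1_sq=h1, h2_sq=h2, rho_k=rho, rho_e=self.rho_e
                    )
                    flat += 1


def default_grid(rho_e: float, n_reps: int = 10_000, seed: int = 0) -> GridSpec:
    """The canonical 10 × 10 × 20 grid with 0.1 spacing (2,000 combinations).

    ``rho_e`` is a required choice: the residual correlation is held at a
    single value across the whole grid to keep the bootstrap tractable, and
    coverage is empirically insensitive to it.
    """
    h = tuple(np.round(np.arange(0.05, 1.0, 0.1), 10))
    rho = tuple(np.round(np.arange(-0.95, 1.0, 0.1), 10))
    return GridSpec(
        h1_values=h, h2_values=h, rho_values=rho, rho_e=rho_e, n_reps=n_reps, seed=seed
    )


@dataclass
class BootstrapStore:
    """Binned estimate counts from a full parametric-bootstrap run.

    ``counts`` has shape (n_h1, n_h2, n_rho, n_h_bins, n_h_bins, n_rho_bins):
    the first three axes index the true-parameter grid combination, the last
    three the estimate bins.  Per combination, counts over estimate bins sum
    to ``valid_reps`` and ``valid_reps + invalid_reps == n_reps``.
    """

    grid: GridSpec
    scheme: BinScheme
    counts: np.ndarray
    valid_reps: np.ndarray
    invalid_reps: np.ndarray
    kinship_checksum: str = ""
    created: str = ""
    package_version: str = ""

    def __post_init__(self):
        expect = self.grid.shape + (
            self.scheme.n_h,
            self.scheme.n_h,
            self.scheme.n_rho,
        )
        if self.counts.shape != expect:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match grid+scheme {expect}"
            )
        if self.valid_reps.shape != self.grid.shape:
            raise ValueError("valid_reps shape must match the grid")
        if self.invalid_reps.shape != self.grid.shape:
            raise ValueError("invalid_reps shape must match the grid")

    def check_conservation(self) -> bool:
        """True iff counts sum to valid_reps and valid+invalid = n_reps everywhere."""
        sums = self.counts.sum(axis=(3, 4, 5))
        return bool(
            np.array_equal(sums, self.valid_reps)
            and np.all(self.valid_reps + self.invalid_reps == self.grid.n_reps)
        )

    def flagged_combinations(self) -> list:
        """Grid indices (i, j, k) with zero valid replicates."""
        return [tuple(ix) for ix in np.argwhere(self.valid_reps == 0)]


def _combo_seed(seed: int, flat_index: int) -> int:
    # stable per-combination seed; < 2**31 so it round-trips everywhere
    return int(
        np.random.SeedSequence((seed, flat_index)).generate_state(1)[0] % (2**31)
    )


def _run_combo(K, W, params, n_reps, seed, scheme):
    draws = draw_pairs(K, params, n_reps, seed)
    h1, h2, rho, valid = estimate_pairs_batch(draws.y1, draws.y2, W)
    nv = int(valid.sum())
    cell = np.zeros((scheme.n_h, scheme.n_h, scheme.n_rho), dtype=np.int64)
    if nv:
        bi = bin_index(h1[valid], "h", scheme)
        bj = bin_index(h2[valid], "h", scheme)
        bk = bin_index(rho[valid], "rho", scheme)
        flat = (bi * scheme.n_h + bj) * scheme.n_rho + bk
        cell = np.bincount(flat, minlength=cell.size).reshape(cell.shape)
    return cell, nv, n_reps - nv


def run_grid(K: KinshipMatrix, grid: GridSpec, workers: int = 1) -> BootstrapStore:
    """Execute the parametric bootstrap over every grid combination.

    Each combination is an independent job seeded from (grid.seed, its flat
    index), so the resulting counts are identical for any ``workers`` count.
    Combinations where every replicate produced an undefined ρ̂ are kept and
    retrievable via :meth:`BootstrapStore.flagged_combinations`.
    """
    W = zero_diagonal_weight(K)
    scheme = grid.scheme
    combos = list(grid.combinations())
    jobs = (
        delayed(_run_combo)(
            K, W, params, grid.n_reps, _combo_seed(grid.seed, flat), scheme
        )
        for flat, _, params in combos
    )
    results = Parallel(n_jobs=workers)(jobs)
    counts = np.zeros(
        grid.shape + (scheme.n_h, scheme.n_h, scheme.n_rho), dtype=np.int64
    )
    valid = np.zeros(grid.shape, dtype=np.int64)
    invalid = np.zeros(grid.shape, dtype=np.int64)
    for (flat, (i, j, k), _), (cell, nv, ni) in zip(combos, results):
        counts[i, j, k] = cell
        valid[i, j, k] = nv
        invalid[i, j, k] = ni
    return BootstrapStore(
        grid=grid,
        scheme=scheme,
        counts=counts,
        valid_reps=valid,
        invalid_reps=invalid,
        kinship_checksum=K.checksum(),
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        package_version=_pkg_version,
    )


# ---------------------------------------------------------------------------
# persistence (HDF5 container)


def save_store(store: BootstrapStore, path) -> None:
    """Write a store to a single HDF5 file (counts + metadata)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=store.counts, compression="gzip", shuffle=True)
        f.create_dataset("valid_reps", data=store.valid_reps)
        f.create_dataset("invalid_reps", data=store.invalid_reps)
        g = f.create_group("grid")
        g.create_dataset("h1_values", data=np.asarray(store.grid.h1_values))
        g.create_dataset("h2_values", data=np.asarray(store.grid.h2_values))
        g.create_dataset("rho_values", data=np.asarray(store.grid.rho_values))
        g.attrs["rho_e"] = store.grid.rho_e
        g.attrs["n_reps"] = store.grid.n_reps
        g.attrs["seed"] = store.grid.seed
        s = f.create_group("scheme")
        s.create_dataset("h_edges", data=store.scheme.h_edges)
        s.create_dataset("rho_edges", data=store.scheme.rho_edges)
        f.attrs["kinship_checksum"] = store.kinship_checksum
        f.attrs["created"] = store.created
        f.attrs["package_version"] = store.package_version


def load_store(path, kinship: KinshipMatrix | None = None) -> BootstrapStore:
    """Load a store; optionally verify it was built on ``kinship``.

    A checksum mismatch when a kinship is supplied produces a warning, not an
    error, because stores are legitimately reused across re-exports of the
    same matrix.
    """
    import warnings

    import h5py

    with h5py.File(path, "r") as f:
        scheme = BinScheme(
            h_edges=f["scheme/h_edges"][()], rho_edges=f["scheme/rho_edges"][()]
        )
        grid = GridSpec(
            h1_values=tuple(f["grid/h1_values"][()]),
            h2_values=tuple(f["grid/h2_values"][()]),
            rho_values=tuple(f["grid/rho_values"][()]),
            rho_e=float(f["grid"].attrs["rho_e"]),
            n_reps=int(f["grid"].attrs["n_reps"]),
            seed=int(f["grid"].attrs["seed"]),
            scheme=scheme,
        )
        store = BootstrapStore(
            grid=grid,
            scheme=scheme,
            counts=f["counts"][()],
            valid_reps=f["valid_reps"][()],
            invalid_reps=f["invalid_reps"][()],
            kinship_checksum=str(f.attrs.get("kinship_checksum", "")),
            created=str(f.attrs.get("created", "")),
            package_version=str(f.attrs.get("package_version", "")),
        )
    if kinship is not None and store.kinship_checksum:
        if kinship.checksum() != store.kinship_checksum:
            warnings.warn(
                "bootstrap store was built on a different kinship matrix "
                "(checksum mismatch)",
                stacklevel=2,
            )
    return store


def merge_stores(a: BootstrapStore, b: BootstrapStore) -> BootstrapStore:
    """Add the counts of two stores built on the same grid (disjoint seeds).

    The merged store reports ``n_reps`` as the sum of the inputs'.
    """
    for attr in ("h1_values", "h2_values", "rho_values", "rho_e"):
        if getattr(a.grid, attr) != getattr(b.grid, attr):
            raise ValueError(f"cannot merge stores with different grid {attr}")
    if a.scheme != b.scheme:
        raise ValueError("cannot merge stores with different bin schemes")
    grid = replace(a.grid, n_reps=a.grid.n_reps + b.grid.n_reps)
    return BootstrapStore(
        grid=grid,
        scheme=a.scheme,
        counts=a.counts + b.counts,
        valid_reps=a.valid_reps + b.valid_reps,
        invalid_reps=a.invalid_reps + b.invalid_reps,
        kinship_checksum=a.kinship_checksum if a.kinship_checksum == b.kinship_checksum else "",
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        package_version=_pkg_version,
    )


def export_long_table(store: BootstrapStore, path) -> None:
    """Write nonzero count cells as a TSV (six bin indices + count)."""
    import pandas as pd

    idx = np.argwhere(store.counts > 0)
    df = pd.DataFrame(
        idx,
        columns=[
            "h1_true_idx",
            "h2_true_idx",
            "rho_true_idx",
            "h1_hat_bin",
            "h2_hat_bin",
            "rho_hat_bin",
        ],
    )
    df["count"] = store.counts[tuple(idx.T)]
    df.to_csv(path, sep="\t", index=False)
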