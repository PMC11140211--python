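"""Genetic-correlation networks across many traits.

The application layer: given a panel of preprocessed traits measured on one
cohort, keep the reliably heritable ones, estimate the HE genetic correlation
and a bootstrap p-value for every pair, adjust the p-values jointly by
Benjamini-Hochberg, and connect pairs whose adjusted p falls below a
threshold.  High-degree nodes ("hubs") are traits genetically correlated with
many others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .estimators import estimate_pair
from .grid_store import BootstrapStore
from .interval import bh_fdr, pvalue_inversion
from .kinship import WeightMatrix
from .pmf import UnsupportedEstimateRegionError, conditional_pmf

__all__ = [
    "TraitPanel",
    "GeneticCorrelationNetwork",
    "filter_heritable",
    "count_pairs",
    "pairwise_genetic_correlations",
    "build_network",
    "pearson_matrix",
]


@dataclass(frozen=True)
class TraitPanel:
    """Preprocessed trait vectors plus per-trait heritability estimates.

    ``phenotypes`` maps trait id → length-n vector (already rank-normalized /
    residualized as appropriate); ``heritabilities`` maps trait id → ĥ².
    """

    trait_ids: tuple
    phenotypes: dict
    heritabilities: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = tuple(str(t) for t in self.trait_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("trait ids must be unique")
        lengths = {len(self.phenotypes[t]) for t in ids}
        if len(lengths) > 1:
            raise ValueError(f"trait vectors have differing lengths: {sorted(lengths)}")
        object.__setattr__(self, "trait_ids", ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)


@dataclass(frozen=True)
class GeneticCorrelationNetwork:
    """FDR-thresholded undirected network of genetically correlated traits."""

    graph: nx.Graph
    fdr_threshold: float
    hubs: tuple  # top-k (trait id, degree), degree-descending, ties by id

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"trait_i": u, "trait_j": v, "rho": d["rho"], "p": d["p"],
             "p_adj": d["p_adj"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["trait_i", "trait_j", "rho", "p", "p_adj", "sign"]
        )

    def degrees(self) -> dict:
        return dict(self.graph.degree())


def filter_heritable(h_hats: dict, lo: float = 0.3, hi: float = 0.9) -> list:
    """Trait ids whose estimated heritability lies in the closed [lo, hi].

    The lower cut drops traits whose genetic correlations and p-values are
    unreliable; the upper cut drops implausibly heritable traits that suggest
    measurement problems.  Boundaries are inclusive.
    """
    return [t for t, h in h_hats.items() if lo <= h <= hi]


def count_pairs(n_traits: int, include_self: bool = False) -> int:
    """Number of trait pairs: n(n−1)/2, or n(n+1)/2 counting self-pairs."""
    if n_traits < 0:
        raise ValueError("n_traits must be >= 0")
    if include_self:
        return n_traits * (n_traits + 1) // 2
    return n_traits * (n_traits - 1) // 2


def pairwise_genetic_correlations(
    panel: TraitPanel,
    W: WeightMatrix,
    store: BootstrapStore | None = None,
    sensitivity: float = 1e-6,
) -> pd.DataFrame:
    """HE genetic correlation and bootstrap p-value for every unordered pair.

    One row per distinct pair (i < j in panel order): trait ids, ĥ² of each,
    ρ̂k, the beta-inversion p-value (NaN when no store is given or the pair's
    estimate cannot be resolved), and a reason string for failed pairs.
    Per-pair failures are recorded, never fatal.
    """
    rows = []
    ids = panel.trait_ids
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ti, tj = ids[a], ids[b]
            trip = estimate_pair(panel.phenotypes[ti], panel.phenotypes[tj], W)
            p = float("nan")
            reason = trip.reason
            if trip.valid and store is not None:
                try:
                    pmf_obj = conditional_pmf(store, trip)
                    p = pvalue_inversion(pmf_obj, method="beta", sensitivity=sensitivity)
                except (UnsupportedEstimateRegionError, ValueError) as exc:
                    reason = str(exc)
            rows.append(
                {"trait_i": ti, "trait_j": tj, "h1_hat": trip.h1_hat,
                 "h2_hat": trip.h2_hat, "rho": trip.rho_hat, "p": p,
                 "valid": trip.valid, "reason": reason}
            )
    return pd.DataFrame(
        rows,
        columns=["trait_i", "trait_j", "h1_hat", "h2_hat", "rho", "p", "valid", "reason"],
    )


def build_network(
    records: pd.DataFrame,
    fdr_threshold: float = 0.01,
    top_k_hubs: int = 10,
) -> GeneticCorrelationNetwork:
    """BH-adjust all pair p-values jointly and keep edges with adjusted p < threshold.

    Nodes are all traits appearing in ``records`` (even if unconnected);
    edges carry ρ̂k, raw and adjusted p, and the correlation sign.  Hubs are
    the ``top_k_hubs`` highest-degree nodes, ties broken by trait id.
    """
    records = records.copy()
    usable = records["p"].notna()
    records["p_adj"] = np.nan
    if usable.any():
        records.loc[usable, "p_adj"] = bh_fdr(records.loc[usable, "p"].to_numpy())
    g = nx.Graph()
    g.add_nodes_from(sorted(set(records["trait_i"]) | set(records["trait_j"])))
    keep = usable & (records["p_adj"] < fdr_threshold)
    for row in records[keep].itertuples():
        if row.trait_i == row.trait_j:
            continue
        g.add_edge(
            row.trait_i,
            row.trait_j,
            rho=row.rho,
            p=row.p,
            p_adj=row.p_adj,
            sign=int(np.sign(row.rho)),
        )
    ranked = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))
    return GeneticCorrelationNetwork(
        graph=g, fdr_threshold=fdr_threshold, hubs=tuple(ranked[:top_k_hubs])
    )


def pearson_matrix(panel: TraitPanel) -> pd.DataFrame:
    """Sample Pearson correlation per unordered pair (phenotypic comparator).

    Zero-variance traits yield NaN with a reason instead of an error.
    """
    rows = []
    ids = panel.trait_ids
    vecs = {t: np.asarray(panel.phenotypes[t], dtype=float) for t in ids}
    sds = {t: vecs[t].std() for t in ids}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ti, tj = ids[a], ids[b]
            if sds[ti] == 0 or sds[tj] == 0:
                rows.append({"trait_i": ti, "trait_j": tj, "pearson": float("nan"),
                             "reason": "zero-variance trait"})
                continue
            r = float(np.corrcoef(vecs[ti], vecs[tj])[0, 1])
            rows.append({"trait_i": ti, "trait_j": tj, "pearson": r, "reason": ""})
    return pd.DataFrame(rows, columns=["trait_i", "trait_j", "pearson", "reason"])


def write_edge_list(net: GeneticCorrelationNetwork, path) -> None:
    """Write edges as tab-delimited text (trait_i, trait_j, rho, p, p_adj, sign)."""
    net.edges.to_csv(path, sep="\t", index=False)


def write_graphml(net: GeneticCorrelationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
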