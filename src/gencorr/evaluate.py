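"""Simulation harness: CI coverage, interval width, and type-1 error.

Method performance is judged by two standard criteria: the coverage
probability (fraction of simulation replicates whose interval contains the
true ρk — ideally at or above the nominal level) and the average interval
width (shorter is better at equal coverage).  Testing is judged by the type-1
error: the rejection rate of H0: ρk = 0 under the null, which should match
the nominal α.

Replicates whose HE estimate is undefined, or whose estimate bins fall
outside the bootstrap store's support, cannot produce an interval; they are
tallied separately and excluded from the denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EstimateTriplet, estimate_pairs_batch
from .grid_store import BootstrapStore
from .interval import ci_beta, ci_fisher, ci_pmf, fit_beta, pvalue_inversion
from .kinship import KinshipMatrix, zero_diagonal_weight
from .pmf import UnsupportedEstimateRegionError, conditional_pmf
from .simulate import TraitPairParams, draw_pairs

__all__ = [
    "CoverageResult",
    "Type1Result",
    "coverage_experiment",
    "type1_experiment",
    "compare_methods_report",
]


@dataclass(frozen=True)
class CoverageResult:
    """Coverage and width of one interval method at one true parameter point."""

    rho_true: float
    method: str
    coverage: float
    mean_width: float
    n_sims: int          # replicates entering the denominator
    n_excluded: int      # undefined estimates / unsupported regions / fit failures
    aggregated_over: str = ""


@dataclass(frozen=True)
class Type1Result:
    """Null rejection rate of the beta-inversion test at one (h1², h2²)."""

    h1_sq: float
    h2_sq: float
    alpha: float
    rejection_rate: float
    n_sims: int
    n_excluded: int


def _interval_for(method, triplet, pmf_obj, alpha, n_eff):
    if callable(method):
        return method(triplet, pmf_obj, alpha)
    if method == "pmf":
        return ci_pmf(pmf_obj, triplet.rho_hat, alpha)
    if method == "beta":
        return ci_beta(fit_beta(pmf_obj), alpha)
    if method == "fisher":
        r = triplet.rho_hat
        # HE estimates can overshoot |rho| = 1 where the z-transform blows up
        r = float(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))
        return ci_fisher(r, n_eff, alpha)
    raise ValueError(f"unknown interval method {method!r}")


def _method_name(method) -> str:
    return method if isinstance(method, str) else getattr(method, "__name__", "custom")


def coverage_experiment(
    K: KinshipMatrix,
    store: BootstrapStore,
    true_params,
    n_sims: int,
    alpha: float = 0.05,
    methods=("pmf", "beta", "fisher"),
    seed: int = 0,
) -> dict:
    """Estimate coverage and mean width per method at fixed true parameters.

    ``true_params`` is a single :class:`TraitPairParams` or a sequence of
    them sharing one ρk (pooled, emulating aggregation over heritability
    scenarios).  Simulates ``n_sims`` replicates per parameter point,
    estimates HE triplets, builds one interval per method and replicate, and
    counts containment of the true ρk.  Returns {method name: CoverageResult}.
    """
    if isinstance(true_params, TraitPairParams):
        scenarios = [true_params]
    else:
        scenarios = list(true_params)
    rhos = {p.rho_k for p in scenarios}
    if len(rhos) != 1:
        raise ValueError("all pooled scenarios must share one true rho_k")
    rho_true = rhos.pop()
    W = zero_diagonal_weight(K)
    n_eff = W.trace_ww

    covered = {_method_name(m): 0 for m in methods}
    width_sum = {_method_name(m): 0.0 for m in methods}
    used = {_method_name(m): 0 for m in methods}
    excluded = {_method_name(m): 0 for m in methods}

    for si, params in enumerate(scenarios):
        draws = draw_pairs(K, params, n_sims, seed=_scenario_seed(seed, si))
        h1, h2, rho, valid = estimate_pairs_batch(draws.y1, draws.y2, W)
        for r in range(n_sims):
            if not valid[r]:
                for m in methods:
                    excluded[_method_name(m)] += 1
                continue
            triplet = EstimateTriplet(
                h1_hat=float(h1[r]), h2_hat=float(h2[r]), rho_hat=float(rho[r])
            )
            try:
                pmf_obj = conditional_pmf(store, triplet)
            except UnsupportedEstimateRegionError:
                for m in methods:
                    excluded[_method_name(m)] += 1
                continue
            for m in methods:
                name = _method_name(m)
                try:
                    ci = _interval_for(m, triplet, pmf_obj, alpha, n_eff)
                except ValueError:
                    excluded[name] += 1
                    continue
                used[name] += 1
                width_sum[name] += ci.width
                if ci.contains(rho_true):
                    covered[name] += 1

    agg = (
        f"{len(scenarios)} heritability scenarios" if len(scenarios) > 1 else ""
    )
    out = {}
    for m in methods:
        name = _method_name(m)
        n = used[name]
        out[name] = CoverageResult(
            rho_true=rho_true,
            method=name,
            coverage=covered[name] / n if n else float("nan"),
            mean_width=width_sum[name] / n if n else float("nan"),
            n_sims=n,
            n_excluded=excluded[name],
            aggregated_over=agg,
        )
    return out


def _scenario_seed(seed: int, scenario_index: int) -> int:
    return int(
        np.random.SeedSequence((seed, 7919, scenario_index)).generate_state(1)[0]
        % (2**31)
    )


def type1_experiment(
    K: KinshipMatrix,
    store: BootstrapStore,
    h1_sq: float,
    h2_sq: float,
    n_sims: int,
    alpha: float = 0.05,
    seed: int = 0,
    rho_e: float = 0.0,
    sensitivity: float = 1e-6,
) -> Type1Result:
    """Null rejection rate of the beta-inversion p-value at (h1², h2², ρk=0).

    Simulates under ρk = 0, computes a p-value per replicate by beta-interval
    inversion, and reports the fraction with p ≤ α among replicates where a
    p-value could be computed.
    """
    params = TraitPairParams(h1_sq=h1_sq, h2_sq=h2_sq, rho_k=0.0, rho_e=rho_e)
    W = zero_diagonal_weight(K)
    draws = draw_pairs(K, params, n_sims, seed=seed)
    h1, h2, rho, valid = estimate_pairs_batch(draws.y1, draws.y2, W)
    rejected = 0
    used = 0
    excluded = 0
    for r in range(n_sims):
        if not valid[r]:
            excluded += 1
            continue
        triplet = EstimateTriplet(
            h1_hat=float(h1[r]), h2_hat=float(h2[r]), rho_hat=float(rho[r])
        )
        try:
            pmf_obj = conditional_pmf(store, triplet)
            p = pvalue_inversion(pmf_obj, method="beta", sensitivity=sensitivity)
        except (UnsupportedEstimateRegionError, ValueError):
            excluded += 1
            continue
        used += 1
        if p <= alpha:
            rejected += 1
    return Type1Result(
        h1_sq=h1_sq,
        h2_sq=h2_sq,
        alpha=alpha,
        rejection_rate=rejected / used if used else float("nan"),
        n_sims=used,
        n_excluded=excluded,
    )


def compare_methods_report(results) -> pd.DataFrame:
    """Long-format table (method × ρ_true × metric) from CoverageResults.

    Deterministically ordered by (method, rho_true, metric); an empty input
    yields an empty table with the standard header.
    """
    rows = []
    for res in results:
        rows.append(
            {"method": res.method, "rho_true": res.rho_true, "metric": "coverage",
             "value": res.coverage, "n_sims": res.n_sims}
        )
        rows.append(
            {"method": res.method, "rho_true": res.rho_true, "metric": "mean_width",
             "value": res.mean_width, "n_sims": res.n_sims}
        )
    df = pd.DataFrame(rows, columns=["method", "rho_true", "metric", "value", "n_sims"])
    if len(df):
        df = df.sort_values(["method", "rho_true", "metric"], kind="stable")
        df = df.reset_index(drop=True)
    return df
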