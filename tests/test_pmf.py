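import numpy as np
import pytest

from gencorr.estimators import EstimateTriplet
from gencorr.grid_store import BootstrapStore, GridSpec
from gencorr.pmf import (
    BinScheme,
    ConditionalPMF,
    UnsupportedEstimateRegionError,
    bin_index,
    conditional_pmf,
)


class TestBinScheme:
    def test_default_axes(self):
        s = BinScheme()
        assert s.n_h == 10 and s.n_rho == 20
        np.testing.assert_allclose(np.diff(s.h_edges), 0.1)
        np.testing.assert_allclose(np.diff(s.rho_edges), 0.1)


class TestBinIndex:
    def test_upper_boundary_belongs_to_last_bin(self):
        # [0.8, 0.9) excludes 0.9, which therefore lands in [0.9, 1]
        assert bin_index(0.9, "rho") == 19
        assert bin_index(0.89999, "rho") == 18

    def test_support_endpoints(self):
        assert bin_index(-1.0, "rho") == 0
        assert bin_index(1.0, "rho") == 19
        assert bin_index(0.0, "h") == 0
        assert bin_index(1.0, "h") == 9

    def test_overshoot_clamps(self):
        assert bin_index(1.07, "h") == 9
        assert bin_index(-0.2, "h") == 0
        assert bin_index(-1.3, "rho") == 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bin_index(float("nan"), "rho")

    def test_array_input(self):
        idx = bin_index(np.array([-0.95, 0.05, 0.95]), "rho")
        np.testing.assert_array_equal(idx, [0, 10, 19])


class TestConditionalPMFType:
    def test_must_sum_to_one(self):
        p = np.zeros(20)
        p[3] = 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            ConditionalPMF(probs=p, observed=(0, 0, 0))

    def test_support_count(self):
        p = np.zeros(20)
        p[[2, 5]] = 0.5
        assert ConditionalPMF(probs=p, observed=(0, 0, 0)).support_count == 2


def make_store(grid, counts, valid=None):
    scheme = grid.scheme
    counts = np.asarray(counts, dtype=np.int64)
    if valid is None:
        valid = counts.sum(axis=(3, 4, 5))
    invalid = grid.n_reps - valid
    return BootstrapStore(
        grid=grid, scheme=scheme, counts=counts, valid_reps=valid,
        invalid_reps=invalid,
    )


def default_shaped_grid(n_reps):
    h = tuple(np.round(np.arange(0.05, 1.0, 0.1), 10))
    rho = tuple(np.round(np.arange(-0.95, 1.0, 0.1), 10))
    return GridSpec(h1_values=h, h2_values=h, rho_values=rho, rho_e=0.0,
                    n_reps=n_reps, seed=0)


class TestConditionalPMF:
    def test_uniform_store_gives_uniform_pmf(self):
        grid = default_shaped_grid(n_reps=10 * 10 * 20)
        counts = np.ones((10, 10, 20, 10, 10, 20), dtype=np.int64)
        store = make_store(grid, counts)
        pm = conditional_pmf(store, EstimateTriplet(0.55, 0.55, 0.45))
        np.testing.assert_allclose(pm.probs, 1 / 20, atol=1e-14)

    def test_two_combination_bayes_ratio(self):
        # p(obs|combo1)=0.3 and p(obs|combo2)=0.1 with distinct true-rho bins
        # -> posterior (0.75, 0.25)
        grid = default_shaped_grid(n_reps=100)
        counts = np.zeros((10, 10, 20, 10, 10, 20), dtype=np.int64)
        obs = (4, 4, 12)
        counts[(2, 2, 5) + obs] = 30
        counts[(2, 2, 9) + obs] = 10
        valid = np.full((10, 10, 20), 100, dtype=np.int64)
        store = make_store(grid, counts, valid=valid)
        pm = conditional_pmf(store, EstimateTriplet(0.45, 0.45, 0.25))
        assert pm.observed == obs
        assert pm.probs[5] == pytest.approx(0.75)
        assert pm.probs[9] == pytest.approx(0.25)
        assert pm.probs.sum() == pytest.approx(1.0)

    def test_unsupported_region_raises(self, tiny_store):
        # an extreme estimate triplet never realized anywhere in a small store
        trip = EstimateTriplet(0.05, 0.05, -0.95)
        counts = tiny_store.counts[:, :, :, 0, 0, 0]
        if counts.sum() == 0:
            with pytest.raises(UnsupportedEstimateRegionError):
                conditional_pmf(tiny_store, trip)

    def test_laplace_smoothing_fills_support(self):
        grid = default_shaped_grid(n_reps=100)
        counts = np.zeros((10, 10, 20, 10, 10, 20), dtype=np.int64)
        valid = np.full((10, 10, 20), 100, dtype=np.int64)
        store = make_store(grid, counts, valid=valid)
        trip = EstimateTriplet(0.55, 0.55, 0.45)
        with pytest.raises(UnsupportedEstimateRegionError):
            conditional_pmf(store, trip)
        pm = conditional_pmf(store, trip, laplace=1.0)
        np.testing.assert_allclose(pm.probs, 1 / 20)

    def test_invalid_estimate_rejected(self, tiny_store):
        trip = EstimateTriplet(0.5, 0.5, float("nan"), valid=False, reason="x")
        with pytest.raises(ValueError, match="invalid estimate"):
            conditional_pmf(tiny_store, trip)

    def test_normalization_on_simulated_store(self, tiny_store):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            trip = EstimateTriplet(
                float(rng.uniform(0, 1)),
                float(rng.uniform(0, 1)),
                float(rng.uniform(-1, 1)),
            )
            try:
                pm = conditional_pmf(tiny_store, trip)
            except UnsupportedEstimateRegionError:
                continue
            hits += 1
            assert pm.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(pm.probs >= 0)
        assert hits > 10


def brute_force_conditional(store, triplet):
    """Materialize the full joint Pr(rho-true bin, estimate bins) and condition.

    Independent of the production path: loops over every grid combination,
    builds the joint table cell by cell with the uniform grid prior, and
    normalizes by explicit summation.
    """
    scheme = store.scheme
    i = bin_index(triplet.h1_hat, "h", scheme)
    j = bin_index(triplet.h2_hat, "h", scheme)
    k = bin_index(triplet.rho_hat, "rho", scheme)
    n_combos = store.grid.n_combinations
    joint = np.zeros(scheme.n_rho)  # Pr(rho-true bin, observed estimate bins)
    for flat, (a, b, c), params in store.grid.combinations():
        nv = store.valid_reps[a, b, c]
        if nv == 0:
            continue
        lik = store.counts[a, b, c, i, j, k] / nv
        joint[bin_index(params.rho_k, "rho", scheme)] += lik / n_combos
    total = joint.sum()
    return joint / total if total > 0 else joint


class TestBruteForceOracle:
    def test_toy_grid_matches_joint_table_conditioning(self, tiny_kinship):
        from gencorr.grid_store import run_grid

        grid = GridSpec(
            h1_values=(0.25, 0.75),
            h2_values=(0.25, 0.75),
            rho_values=(-0.55, 0.05, 0.65),
            rho_e=0.0,
            n_reps=300,
            seed=21,
        )
        store = run_grid(tiny_kinship, grid)
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(30):
            trip = EstimateTriplet(
                float(rng.uniform(0, 1)),
                float(rng.uniform(0, 1)),
                float(rng.uniform(-1, 1)),
            )
            expected = brute_force_conditional(store, trip)
            if expected.sum() == 0:
                continue
            pm = conditional_pmf(store, trip)
            np.testing.assert_allclose(pm.probs, expected, atol=1e-12)
            checked += 1
        assert checked > 5
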