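import numpy as np
import pytest

from gencorr.interval import (
    BetaFit,
    bh_fdr,
    ci_beta,
    ci_fisher,
    ci_pmf,
    fit_beta,
    pmf_cdf,
    pvalue_inversion,
)
from gencorr.pmf import BinScheme, ConditionalPMF

from conftest import random_pmfs


def pmf_from(probs):
    p = np.zeros(20)
    p[: len(probs)] = probs
    return ConditionalPMF(probs=p / p.sum(), observed=(0, 0, 0))


def pmf_at(bin_probs: dict):
    p = np.zeros(20)
    for b, mass in bin_probs.items():
        p[b] = mass
    return ConditionalPMF(probs=p / p.sum(), observed=(0, 0, 0))


UNIFORM = ConditionalPMF(probs=np.full(20, 1 / 20), observed=(0, 0, 0))


class TestPmfCdf:
    def test_extremes(self):
        pm = pmf_at({10: 1.0})
        assert pmf_cdf(pm, -1.0) == 0.0
        assert pmf_cdf(pm, 1.0) == 1.0
        assert pmf_cdf(pm, -0.5) == 0.0  # below all mass
        assert pmf_cdf(pm, 0.5) == 1.0  # above all mass

    def test_uniform_midpoint(self):
        assert pmf_cdf(UNIFORM, 0.0) == pytest.approx(0.5)

    def test_linear_interpolation_within_bin(self):
        # bin [0.0, 0.1) holds 0.4 mass; halfway through it adds 0.2
        pm = pmf_at({8: 0.3, 10: 0.4, 12: 0.3})
        assert pmf_cdf(pm, 0.05) == pytest.approx(pmf_cdf(pm, 0.0) + 0.2)

    def test_nondecreasing(self):
        for pm in random_pmfs(10, seed=4):
            xs = np.linspace(-1, 1, 101)
            cdf = [pmf_cdf(pm, x) for x in xs]
            assert np.all(np.diff(cdf) >= -1e-15)


class TestCiPmf:
    def test_support_containment_single_bin(self):
        pm = pmf_at({18: 1.0})  # all mass in [0.8, 0.9)
        for alpha in (0.01, 0.05, 0.2):
            ci = ci_pmf(pm, 0.85, alpha)
            assert 0.8 <= ci.lower <= ci.upper <= 0.9

    def test_uniform_equal_tail(self):
        ci = ci_pmf(UNIFORM, 0.0, 0.05)
        assert ci.case == "3"
        assert ci.lower == pytest.approx(-0.95)
        assert ci.upper == pytest.approx(0.95)

    def test_boundary_pileup_case2(self):
        # estimate deep in the upper tail: under 2.5% of mass lies above it,
        # so the equal upper tail is infeasible and the interval runs to the
        # support's upper end
        pm = pmf_at({19: 0.97, 18: 0.02, 17: 0.01})
        ci = ci_pmf(pm, 0.999, 0.05)
        assert ci.case == "2"
        assert ci.upper == 1.0
        assert pmf_cdf(pm, ci.upper) - pmf_cdf(pm, ci.lower) >= 0.95 - 1e-12

    def test_boundary_pileup_case1(self):
        pm = pmf_at({0: 0.97, 1: 0.02, 2: 0.01})
        ci = ci_pmf(pm, -0.999, 0.05)
        assert ci.case == "1"
        assert ci.lower == -1.0

    def test_case_labels_match_cpl(self):
        for pm in random_pmfs(40, seed=9):
            for rho_hat in (-0.99, -0.3, 0.0, 0.4, 0.99):
                ci = ci_pmf(pm, rho_hat, 0.05)
                cpl = pmf_cdf(pm, rho_hat)
                if cpl < 0.025:
                    assert ci.case == "1"
                elif 1 - cpl < 0.025:
                    assert ci.case == "2"
                else:
                    assert ci.case == "3"

    def test_mass_guarantee_and_bounds(self):
        for pm in random_pmfs(60, seed=2):
            for alpha in (0.01, 0.05, 0.1):
                ci = ci_pmf(pm, 0.1, alpha)
                assert -1 <= ci.lower <= ci.upper <= 1
                mass = pmf_cdf(pm, ci.upper) - pmf_cdf(pm, ci.lower)
                assert mass >= 1 - alpha - 1e-9

    def test_nesting_across_levels(self):
        for pm in random_pmfs(30, seed=6):
            tight = ci_pmf(pm, 0.2, 0.10)
            wide = ci_pmf(pm, 0.2, 0.01)
            assert wide.lower <= tight.lower + 1e-12
            assert wide.upper >= tight.upper - 1e-12

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            ci_pmf(UNIFORM, 0.0, 0.0)


class TestBetaFit:
    def test_symmetric_pmf_equal_shapes(self):
        pm = pmf_at({8: 0.2, 9: 0.3, 10: 0.3, 11: 0.2})
        fit = fit_beta(pm)
        assert fit.a == pytest.approx(fit.b)

    def test_uniform_moment_oracle(self):
        # discrete uniform over the 20 transformed midpoints
        mids = (BinScheme().rho_midpoints() + 1) / 2
        mu, v = mids.mean(), mids.var()
        expect = mu * (mu * (1 - mu) / v - 1)
        assert v == pytest.approx((1 - 1 / 20**2) / 12)
        fit = fit_beta(UNIFORM)
        assert fit.a == pytest.approx(expect)
        assert fit.b == pytest.approx(expect)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="degenerate PMF"):
            fit_beta(pmf_at({5: 1.0}))

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            BetaFit(a=-1.0, b=2.0)


class TestCiBeta:
    def test_symmetric_shapes_symmetric_interval(self):
        ci = ci_beta(BetaFit(a=5.0, b=5.0), 0.05)
        assert ci.lower == pytest.approx(-ci.upper)

    def test_uniform_beta_quantiles(self):
        ci = ci_beta(BetaFit(a=1.0, b=1.0), 0.05)
        assert ci.lower == pytest.approx(2 * 0.025 - 1)
        assert ci.upper == pytest.approx(2 * 0.975 - 1)

    def test_ordering_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            fit = BetaFit(a=rng.uniform(0.2, 50), b=rng.uniform(0.2, 50))
            ci = ci_beta(fit, rng.uniform(0.001, 0.5))
            assert ci.lower < ci.upper


class TestCiFisher:
    def test_zero_estimate_symmetric(self):
        from scipy.stats import norm

        ci = ci_fisher(0.0, 103, 0.05)
        half = np.tanh(norm.ppf(0.975) / 10.0)
        assert ci.lower == pytest.approx(-half)
        assert ci.upper == pytest.approx(half)

    def test_textbook_example(self):
        # z = arctanh(0.5) = 0.5493, sigma = 1/sqrt(100) = 0.1
        ci = ci_fisher(0.5, 103, 0.05)
        assert ci.lower == pytest.approx(np.tanh(0.54931 - 1.95996 * 0.1), abs=1e-4)
        assert ci.upper == pytest.approx(np.tanh(0.54931 + 1.95996 * 0.1), abs=1e-4)
        assert ci.lower == pytest.approx(0.3393, abs=2e-4)
        assert ci.upper == pytest.approx(0.6324, abs=2e-4)

    def test_guards(self):
        with pytest.raises(ValueError, match="n_eff"):
            ci_fisher(0.2, 3.0, 0.05)
        with pytest.raises(ValueError, match="boundary"):
            ci_fisher(1.0, 100, 0.05)


class TestPvalueInversion:
    def test_symmetric_pmf_p_near_one(self):
        pm = pmf_at({9: 0.5, 10: 0.5})
        assert pvalue_inversion(pm, method="beta") == 1.0

    def test_mass_far_from_zero_hits_floor(self):
        pm = pmf_at({16: 0.5, 17: 0.5})  # all mass in [0.6, 0.8)
        p = pvalue_inversion(pm, method="beta", sensitivity=1e-6)
        assert p == pytest.approx(1e-6)

    def test_bisection_matches_grid_scan(self):
        for pm in random_pmfs(10, seed=12):
            sens = 1e-3
            p = pvalue_inversion(pm, method="beta", sensitivity=sens)
            fit_alphas = np.arange(sens, 1.0, sens)
            from gencorr.interval import fit_beta as _fit

            fit = _fit(pm)
            exclude = [
                a for a in fit_alphas
                if (lambda ci: ci.lower > 0 or ci.upper < 0)(ci_beta(fit, a))
            ]
            expect = exclude[0] if exclude else 1.0
            assert p == pytest.approx(expect, abs=2 * sens)

    def test_pmf_method_consistent_with_interval(self):
        pm = pmf_at({12: 0.6, 13: 0.3, 14: 0.1})
        p = pvalue_inversion(pm, method="pmf", sensitivity=1e-4, rho_hat=0.28)
        ci_at_p = ci_pmf(pm, 0.28, min(p + 1e-4, 0.999))
        assert ci_at_p.lower > 0 or ci_at_p.upper < 0


class TestBhFdr:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_equal_values_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_order_preserved(self):
        np.testing.assert_allclose(
            bh_fdr([0.04, 0.01, 0.02]), [0.04, 0.03, 0.03]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
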