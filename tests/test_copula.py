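"""Numerics of the Gaussian copula with binomial margins."""

import numpy as np
import pytest
from scipy.stats import binom, multivariate_normal
from scipy.special import ndtri

from copulameta import (BinomialMargin, CopulaParam, bivariate_binomial_pmf,
                        log_bivariate_binomial_pmf, normal_copula_cdf,
                        owens_t, sample_bernoulli_pair)
from copulameta.copula import _copula_cdf_formula


def phi2(u1, u2, rho):
    """Independent oracle: bivariate normal CDF via scipy's quadrature."""
    if u1 <= 0 or u2 <= 0:
        return 0.0
    if u1 >= 1:
        return u2
    if u2 >= 1:
        return u1
    mv = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
    return float(mv.cdf([ndtri(u1), ndtri(u2)]))


class TestOwensT:
    def test_zero_slope_is_zero(self):
        assert owens_t(2.3, 0.0) == 0.0

    def test_closed_form_at_origin(self):
        # T(0, a) = arctan(a) / (2 pi)
        assert owens_t(0.0, 1.0) == pytest.approx(0.125, abs=1e-12)
        assert owens_t(0.0, 0.3) == pytest.approx(np.arctan(0.3) / (2 * np.pi),
                                                  abs=1e-12)

    def test_even_in_h_odd_in_a(self):
        assert owens_t(-1.1, 0.7) == pytest.approx(owens_t(1.1, 0.7), abs=1e-15)
        assert owens_t(1.1, -0.7) == pytest.approx(-owens_t(1.1, 0.7), abs=1e-15)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            owens_t(np.nan, 0.5)
        with pytest.raises(ValueError):
            owens_t(0.5, np.inf)


class TestNormalCopulaCdf:
    def test_independence_product(self):
        assert normal_copula_cdf(0.3, 0.6, 0.0) == pytest.approx(0.18, abs=1e-12)

    def test_median_point_closed_form(self):
        # C(1/2, 1/2; rho) = 1/4 + arcsin(rho) / (2 pi)
        want = 0.25 + np.arcsin(0.6) / (2 * np.pi)
        assert normal_copula_cdf(0.5, 0.5, 0.6) == pytest.approx(want, abs=1e-10)
        assert want == pytest.approx(0.35242, abs=5e-5)

    def test_grounded_and_uniform_margins(self):
        assert normal_copula_cdf(0.0, 0.7, 0.4) == 0.0
        assert normal_copula_cdf(1.0, 0.7, 0.4) == pytest.approx(0.7, abs=0)
        assert normal_copula_cdf(0.7, 1.0, -0.2) == pytest.approx(0.7, abs=0)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            normal_copula_cdf(-0.1, 0.5, 0.0)
        with pytest.raises(ValueError):
            normal_copula_cdf(0.5, 1.1, 0.0)
        with pytest.raises(ValueError):
            normal_copula_cdf(0.5, 0.5, 1.0)

    @pytest.mark.parametrize("u1,u2,rho", [
        (0.3, 0.6, 0.5), (0.9, 0.1, -0.8), (0.5, 0.7, 0.3), (0.2, 0.5, -0.4),
        (0.05, 0.95, 0.9), (0.5, 0.5, -0.95), (0.65, 0.65, 0.99),
    ])
    def test_matches_quadrature_oracle(self, u1, u2, rho):
        assert normal_copula_cdf(u1, u2, rho) == pytest.approx(
            phi2(u1, u2, rho), abs=1e-6)

    def test_frechet_bounds_on_random_triples(self):
        rng = np.random.default_rng(7)
        u1 = rng.random(10_000)
        u2 = rng.random(10_000)
        rho = rng.uniform(-1 + 1e-6, 1 - 1e-6, 10_000)
        c = normal_copula_cdf(u1, u2, rho)
        assert np.all(c >= np.maximum(0.0, u1 + u2 - 1.0))
        assert np.all(c <= np.minimum(u1, u2))

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(8)
        u1, u2 = rng.random(500), rng.random(500)
        rho = rng.uniform(-0.99, 0.99, 500)
        np.testing.assert_allclose(normal_copula_cdf(u1, u2, rho),
                                   normal_copula_cdf(u2, u1, rho), atol=1e-13)

    def test_fast_formula_agrees_with_careful_path(self):
        rng = np.random.default_rng(9)
        u1 = np.concatenate([rng.random(2000), [0.5, 0.5, 1e-12, 1 - 1e-12]])
        u2 = np.concatenate([rng.random(2000), [0.5, 0.2, 0.4, 0.9]])
        rho = np.concatenate([rng.uniform(-0.99, 0.99, 2000), [0.6, 0.3, 0.9, -0.9]])
        np.testing.assert_allclose(_copula_cdf_formula(u1, u2, rho),
                                   normal_copula_cdf(u1, u2, rho), atol=1e-12)


class TestBivariateBinomialPmf:
    def test_independence_factorises(self):
        m1, m2 = BinomialMargin(10, 0.4), BinomialMargin(10, 0.6)
        want = binom.pmf(3, 10, 0.4) * binom.pmf(5, 10, 0.6)
        got = bivariate_binomial_pmf(3, 5, m1, m2, 0.0, floor=None)
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("n,p1,p2,rho", [
        (8, 0.3, 0.9, 0.7), (20, 0.5, 0.5, -0.6), (50, 0.1, 0.8, 0.4),
        (50, 0.95, 0.95, 0.9), (35, 0.5, 0.2, -0.9),
    ])
    def test_normalisation_pre_clamp(self, n, p1, p2, rho):
        m1, m2 = BinomialMargin(n, p1), BinomialMargin(n, p2)
        r1, r2 = np.meshgrid(np.arange(n + 1), np.arange(n + 1))
        h = bivariate_binomial_pmf(r1, r2, m1, m2, rho, floor=None)
        assert h.sum() == pytest.approx(1.0, abs=1e-8)
        assert h.min() > -1e-10  # cancellation noise only

    def test_exchange_symmetry(self):
        m1, m2 = BinomialMargin(12, 0.3), BinomialMargin(9, 0.7)
        r1, r2 = np.meshgrid(np.arange(13), np.arange(10), indexing="ij")
        a = bivariate_binomial_pmf(r1, r2, m1, m2, 0.45)
        b = bivariate_binomial_pmf(r2.T, r1.T, m2, m1, 0.45)
        np.testing.assert_allclose(a, b.T, atol=1e-12)

    def test_comonotone_limit_concentrates_on_diagonal(self):
        m = BinomialMargin(6, 0.5)
        diag = lambda rho: sum(bivariate_binomial_pmf(r, r, m, m, rho)
                               for r in range(7))
        masses = [diag(r) for r in (0.9, 0.999, 0.999999)]
        assert masses == sorted(masses)
        assert masses[-1] >= 0.99

    def test_out_of_support_errors(self):
        m = BinomialMargin(5, 0.5)
        with pytest.raises(ValueError):
            bivariate_binomial_pmf(6, 0, m, m, 0.2)
        with pytest.raises(ValueError):
            bivariate_binomial_pmf(0, -1, m, m, 0.2)

    def test_margins_are_exactly_binomial(self):
        m1, m2 = BinomialMargin(7, 0.35), BinomialMargin(7, 0.8)
        r1, r2 = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        h = bivariate_binomial_pmf(r1, r2, m1, m2, 0.65, floor=None)
        np.testing.assert_allclose(h.sum(axis=1), binom.pmf(np.arange(8), 7, 0.35),
                                   atol=1e-10)
        np.testing.assert_allclose(h.sum(axis=0), binom.pmf(np.arange(8), 7, 0.8),
                                   atol=1e-10)

    def test_aggregate_law_vs_summed_bernoulli_pairs(self):
        """At n=1 the copula-coupled binomial pmf coincides exactly with the
        law of a single Gaussian-copula Bernoulli pair (latent quadrant
        probabilities); for n >= 2 the two constructions are genuinely
        different laws (sums of coupled pairs are not themselves
        copula-coupled binomials), which is why aggregate-level dependence
        has to be re-estimated rather than carried over from the IPD level."""
        p1, p2, rho = 0.4, 0.6, 0.5
        q11 = p1 + p2 - 1 + phi2(1 - p1, 1 - p2, rho)
        cells = {(1, 1): q11, (1, 0): p1 - q11, (0, 1): p2 - q11,
                 (0, 0): 1 - p1 - p2 + q11}
        m1, m2 = BinomialMargin(1, p1), BinomialMargin(1, p2)
        for (r1, r2), q in cells.items():
            assert bivariate_binomial_pmf(r1, r2, m1, m2, rho, floor=None) == \
                pytest.approx(q, abs=1e-9)
        # n = 2: exhaustive enumeration of summed pairs differs measurably
        pair = np.array([[cells[(1, 1)], cells[(1, 0)]],
                         [cells[(0, 1)], cells[(0, 0)]]])
        conv = np.zeros((3, 3))
        for (a1, a2) in [(i, j) for i in (0, 1) for j in (0, 1)]:
            for (b1, b2) in [(i, j) for i in (0, 1) for j in (0, 1)]:
                conv[a1 + b1, a2 + b2] += pair[1 - a1, 1 - a2] * pair[1 - b1, 1 - b2]
        m1, m2 = BinomialMargin(2, p1), BinomialMargin(2, p2)
        r1, r2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        agg = bivariate_binomial_pmf(r1, r2, m1, m2, rho, floor=None)
        assert np.abs(agg - conv).max() > 1e-4


class TestLogPmf:
    def test_round_trips_with_pmf(self):
        m1, m2 = BinomialMargin(19, 0.45), BinomialMargin(19, 0.7)
        r1, r2 = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        lp = log_bivariate_binomial_pmf(r1, r2, m1, m2, 0.55)
        p = bivariate_binomial_pmf(r1, r2, m1, m2, 0.55)
        np.testing.assert_allclose(np.exp(lp), p, atol=1e-12)
        assert np.all(np.isfinite(lp))

    def test_independence_equals_sum_of_binomial_logpmfs(self):
        m1, m2 = BinomialMargin(15, 0.3), BinomialMargin(15, 0.8)
        lp = log_bivariate_binomial_pmf(4, 12, m1, m2, 0.0)
        want = binom.logpmf(4, 15, 0.3) + binom.logpmf(12, 15, 0.8)
        assert lp == pytest.approx(want, abs=1e-9)

    def test_likelihood_prefers_generating_dependence(self):
        rng = np.random.default_rng(11)
        n, K = 30, 400
        m = BinomialMargin(n, 0.5)
        counts = np.array([sample_bernoulli_pair(0.5, 0.5, 0.7, n, rng).sum(axis=0)
                           for _ in range(K)])
        ll = lambda rho: np.sum(log_bivariate_binomial_pmf(
            counts[:, 0], counts[:, 1], m, m, rho))
        assert ll(0.7) > ll(-0.7)


class TestSampleBernoulliPair:
    def test_marginal_means_within_three_ses(self):
        x = sample_bernoulli_pair(0.3, 0.8, 0.5, 40_000, seed=1)
        for j, p in enumerate([0.3, 0.8]):
            se = np.sqrt(p * (1 - p) / 40_000)
            assert abs(x[:, j].mean() - p) < 3 * se

    def test_independence_gives_vanishing_correlation(self):
        x = sample_bernoulli_pair(0.5, 0.5, 0.0, 50_000, seed=2)
        assert abs(np.corrcoef(x[:, 0], x[:, 1])[0, 1]) < 0.015

    def test_joint_cell_matches_copula_cdf(self):
        x = sample_bernoulli_pair(0.5, 0.5, 0.9, 100_000, seed=3)
        both = np.mean((x[:, 0] == 1) & (x[:, 1] == 1))
        want = normal_copula_cdf(0.5, 0.5, 0.9)
        assert both == pytest.approx(want, abs=0.005)

    def test_reproducible_and_validated(self):
        a = sample_bernoulli_pair(0.4, 0.6, 0.3, 100, seed=5)
        b = sample_bernoulli_pair(0.4, 0.6, 0.3, 100, seed=5)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            sample_bernoulli_pair(0.4, 0.6, 0.3, 0, seed=5)
        with pytest.raises(ValueError):
            sample_bernoulli_pair(0.0, 0.6, 0.3, 10, seed=5)


class TestDomainTypes:
    def test_margin_cdf_endpoints_exact(self):
        m = BinomialMargin(9, 0.42)
        assert m.cdf(-1) == 0.0
        assert m.cdf(9) == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BinomialMargin(0, 0.5)
        with pytest.raises(ValueError):
            BinomialMargin(5, 1.0)
        with pytest.raises(ValueError):
            CopulaParam(1.0)
        assert CopulaParam(0.3).rho == 0.3
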