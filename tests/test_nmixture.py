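"""N-mixture likelihood, fitting, sampling and diagnostics."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit, logit, logsumexp

from biopyramid.errors import ModelError
from biopyramid.nmixture import (
    NMixtureModel,
    PosteriorDraws,
    PriorSpec,
    fit_mle,
    gelman_rubin,
    mean_relative_abundance,
    sample_posterior,
)

from conftest import make_history, naive_marginal_loglik


def intercept_model(counts, K=None, **kw):
    return NMixtureModel(make_history(counts), effort_covariate=False, K=K, **kw)


class TestMarginalLoglik:
    def test_all_zero_single_visit_closed_form(self):
        # P(y=0) for one visit = exp(-lambda * p)
        m = intercept_model([[0.0]], K=300)
        assert m.loglik([0.0, logit(0.5)]) == pytest.approx(-0.5, abs=1e-12)

    def test_single_visit_is_poisson_thinning(self):
        m = intercept_model([[1.0]], K=300)
        assert m.loglik([np.log(2.0), logit(0.5)]) == pytest.approx(
            stats.poisson.logpmf(1, 1.0), abs=1e-10
        )

    def test_two_occasion_example_matches_brute_force(self):
        counts = np.array([[1.0, 2.0]])
        m = intercept_model(counts, K=500)
        theta = [np.log(3.0), logit(0.4)]
        oracle = naive_marginal_loglik(counts, np.ones_like(counts, bool),
                                       np.full_like(counts, 0.4), [3.0], 500)
        assert m.loglik(theta) == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n, T = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            lam = float(rng.uniform(0.2, 4.0))
            counts = rng.poisson(lam, (n, T)).astype(float)
            effort = rng.integers(1, 6, (n, T))
            h = make_history(counts, effort)
            K = int(counts.max()) + 30
            m = NMixtureModel(h, effort_covariate=True, K=K)
            g0, g1 = float(rng.normal(-1, 0.5)), float(rng.normal(0.5, 0.3))
            p = expit(g0 + g1 * effort / 5.0)
            ours = m.loglik([np.log(lam), g0, g1])
            oracle = naive_marginal_loglik(counts, effort > 0, p, [lam] * n, K)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_missing_occasions_excluded(self):
        counts = np.array([[2.0, 0.0]])
        effort = np.array([[5, 0]])
        m = NMixtureModel(make_history(counts, effort), effort_covariate=False, K=200)
        m1 = intercept_model([[2.0]], K=200)
        theta = [np.log(2.0), logit(0.3)]
        assert m.loglik(theta) == pytest.approx(m1.loglik(theta), abs=1e-12)

    def test_truncation_below_max_count_rejected(self):
        with pytest.raises(ModelError):
            intercept_model([[5.0]], K=3)

    def test_nonfinite_parameter_rejected(self):
        m = intercept_model([[1.0]], K=50)
        with pytest.raises(ModelError):
            m.loglik([np.nan, 0.0])

    @given(lam=st.floats(0.1, 8.0), p=st.floats(0.02, 0.98),
           y=st.integers(0, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_single_occasion_marginal_is_poisson_thinned(self, lam, p, y):
        m = intercept_model([[float(y)]], K=int(lam + 10 * math.sqrt(lam) + 60))
        assert m.loglik([np.log(lam), logit(p)]) == pytest.approx(
            stats.poisson.logpmf(y, lam * p), rel=1e-9, abs=1e-9
        )

    def test_normalization_over_y(self):
        lam, p = 3.0, 0.4
        K = int(lam + 10 * math.sqrt(lam) + 50)
        total = 0.0
        for y in range(K + 1):
            m = intercept_model([[float(y)]], K=K)
            total += math.exp(m.loglik([np.log(lam), logit(p)]))
        assert total >= 0.9999

    def test_loglik_nondecreasing_and_stable_in_K(self):
        counts = np.array([[1.0, 3.0], [0.0, 2.0]])
        theta = [np.log(2.5), logit(0.3)]
        vals = [intercept_model(counts, K=K).loglik(theta) for K in (3, 5, 10, 20, 60, 120)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] - vals[-2] < 1e-8
        # the automatic bound has itself stabilized
        m_auto = intercept_model(counts)
        assert m_auto.loglik(theta) == pytest.approx(vals[-1], abs=1e-7)


class TestMLE:
    def test_perfect_detection_reduces_to_poisson_mle(self):
        rng = np.random.default_rng(5)
        N = rng.poisson(3.0, 40)
        counts = np.tile(N[:, None], (1, 4)).astype(float)  # p=1: y == N always
        h = make_history(counts)
        fit = fit_mle(h, effort_covariate=False, fixed_gamma=[np.inf])
        lam_hat = math.exp(fit.theta[0])
        assert lam_hat == pytest.approx(N.mean(), rel=1e-4)

    def test_matches_grid_search_oracle_on_tiny_data(self):
        counts = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]])
        fit = fit_mle(make_history(counts), effort_covariate=False, K=60)
        assert fit.converged
        b_grid = fit.theta[0] + np.arange(-50, 51) * 0.001
        g_grid = fit.theta[1] + np.arange(-50, 51) * 0.001
        best = -np.inf
        for b in b_grid:
            for g in g_grid:
                ll = naive_marginal_loglik(counts, np.ones_like(counts, bool),
                                           np.full_like(counts, expit(g)),
                                           [math.exp(b)] * 2, 60)
                best = max(best, ll)
        assert fit.loglik >= best - 1e-9

    def test_recovers_simulated_parameters_within_three_se(self):
        rng = np.random.default_rng(123)
        n, T, lam, p = 200, 6, 2.0, 0.4
        counts = rng.binomial(rng.poisson(lam, n)[:, None], p, (n, T)).astype(float)
        fit = fit_mle(make_history(counts), effort_covariate=False)
        lam_hat = math.exp(fit.theta[0])
        se_lam = lam_hat * fit.se[0]  # delta method on the log scale
        assert abs(lam_hat - lam) < 3 * se_lam

    def test_nonconvergence_is_flagged_not_raised(self):
        # a single unit, single occasion: ridge lambda*p, BFGS wanders
        fit = fit_mle(make_history([[1.0]]), effort_covariate=False, K=80)
        assert isinstance(fit.converged, bool)  # result returned either way
        assert fit.message


class TestPosterior:
    def test_same_seed_gives_identical_draws(self):
        m = intercept_model([[1.0, 0.0], [2.0, 1.0]], K=60)
        d1 = sample_posterior(m, chains=2, iterations=300, burn_in=150, seed=9)
        d2 = sample_posterior(m, chains=2, iterations=300, burn_in=150, seed=9)
        assert np.array_equal(d1.draws, d2.draws)
        d3 = sample_posterior(m, chains=2, iterations=300, burn_in=150, seed=10)
        assert not np.array_equal(d1.draws, d3.draws)

    def test_default_shape_matches_protocol(self):
        m = intercept_model([[1.0, 0.0]], K=40)
        d = sample_posterior(m, iterations=40, burn_in=20, seed=0)
        assert d.draws.shape == (4, 20, 2)
        d_full_settings = dict(chains=4, iterations=4000, burn_in=2000)
        assert d_full_settings["iterations"] - d_full_settings["burn_in"] == 2000

    def test_posterior_means_match_grid_quadrature(self):
        rng = np.random.default_rng(2)
        counts = rng.binomial(rng.poisson(2.0, 10)[:, None], 0.5, (10, 4)).astype(float)
        m = intercept_model(counts, K=50)
        prior = PriorSpec(0.0, 10.0)
        # independent dense-grid quadrature of the 2-parameter posterior
        b = np.linspace(-1.5, 2.5, 100)
        g = np.linspace(-3.0, 3.0, 100)
        logpost = np.empty((len(b), len(g)))
        for i, bi in enumerate(b):
            for j, gj in enumerate(g):
                logpost[i, j] = (
                    naive_marginal_loglik(counts, np.ones_like(counts, bool),
                                          np.full_like(counts, expit(gj)),
                                          [math.exp(bi)] * 10, 50)
                    + stats.norm.logpdf(bi, 0, 10) + stats.norm.logpdf(gj, 0, 10)
                )
        w = np.exp(logpost - logsumexp(logpost))
        b_mean = float((w.sum(axis=1) * b).sum())
        g_mean = float((w.sum(axis=0) * g).sum())
        d = sample_posterior(m, prior=prior, chains=4, iterations=8000, burn_in=3000, seed=4)
        flat = d.flat()
        assert flat[:, 0].mean() == pytest.approx(b_mean, abs=0.1)
        assert flat[:, 1].mean() == pytest.approx(g_mean, abs=0.15)

    def test_improper_prior_rejected(self):
        with pytest.raises(ModelError):
            PriorSpec(0.0, 0.0)

    def test_single_chain_rejected(self):
        m = intercept_model([[1.0]], K=40)
        with pytest.raises(ModelError):
            sample_posterior(m, chains=1, iterations=100, burn_in=50, seed=0)


def toy_draws(arrays, names=None):
    x = np.asarray(arrays, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    names = names or [f"p{i}" for i in range(x.shape[2])]
    return PosteriorDraws(draws=x, parameter_names=names, seed=0,
                         settings={}, accept_rate=np.ones(x.shape[0]))


class TestGelmanRubin:
    def test_identical_chains_give_sqrt_n_minus_1_over_n(self):
        # hand calculation: W=1, B=0 -> rhat = sqrt((n-1)/n) = sqrt(2/3)
        d = toy_draws(np.tile([[1.0, 2.0, 3.0]], (2, 1)))
        d.draws = np.broadcast_to(np.array([1.0, 2.0, 3.0])[None, :, None], (2, 3, 1)).copy()
        with pytest.raises(ModelError):
            gelman_rubin(d)  # fewer than 10 iterations
        seq = np.arange(10.0)
        d = toy_draws(np.stack([seq, seq]))
        rep = gelman_rubin(d)
        assert rep.rhat.iloc[0] == pytest.approx(math.sqrt(9 / 10), abs=1e-12)
        assert any("< 1" in n for n in rep.notes)

    def test_iid_normal_chains_converged(self):
        rng = np.random.default_rng(0)
        d = toy_draws(rng.standard_normal((4, 2000)))
        rep = gelman_rubin(d)
        assert rep.rhat.iloc[0] < 1.01
        assert rep.converged

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 500))
        x[1] += 100.0
        rep = gelman_rubin(toy_draws(x))
        assert rep.rhat.iloc[0] > 10
        assert rep.flags == ["p0"]

    def test_zero_variance_everywhere_is_undefined_not_crash(self):
        rep = gelman_rubin(toy_draws(np.zeros((2, 50))))
        assert np.isnan(rep.rhat.iloc[0])
        assert rep.flags == ["p0"]


class TestMeanRelativeAbundance:
    def test_constant_draws_at_zero_give_one_per_station(self):
        m = intercept_model([[1.0], [0.0]], K=40)
        d = toy_draws(np.zeros((2, 50, 2)), names=m.parameter_names)
        est = mean_relative_abundance(d, m)
        assert est.mean_relative_abundance == pytest.approx(1.0)
        assert est.interval == (pytest.approx(1.0), pytest.approx(1.0))

    def test_camera_effects_average_lambda_over_units(self):
        h = make_history([[1.0], [0.0]], stations=["a", "b"])
        m = NMixtureModel(h, camera_effects=True, effort_covariate=False, K=40)
        # intercept 0, station-b effect -log 2... reference coding: lambda_a=exp(0+?)...
        theta = np.zeros((2, 12, m.n_params))
        theta[:, :, m.parameter_names.index("beta:station[b]")] = -np.log(4.0)
        theta[:, :, 0] = np.log(2.0)
        est = mean_relative_abundance(toy_draws(theta, m.parameter_names), m)
        assert est.mean_relative_abundance == pytest.approx((2.0 + 0.5) / 2)

    def test_single_unit_average_is_that_unit(self):
        m = intercept_model([[2.0, 1.0]], K=60)
        rng = np.random.default_rng(3)
        d = toy_draws(rng.normal(0.3, 0.05, (2, 200, 2)), names=m.parameter_names)
        est = mean_relative_abundance(d, m)
        assert est.mean_relative_abundance == pytest.approx(
            est.per_unit_lambda.iloc[0], rel=1e-12
        )
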