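"""Priors, likelihood, ESS, IMIS machinery and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crcuq as c
from crcuq.calibration import (BetaMarginal, LikelihoodEvaluator,
                               LognormalMarginal, NormalMarginal,
                               PosteriorSample, PriorSpec, default_prior,
                               effective_sample_size, log_prior, map_estimate,
                               posterior_predictive, posterior_summary,
                               run_imis)


class TestPrior:
    def test_beta_term_value(self):
        # Beta(3, 8) log density at 0.25, via exact log-gamma arithmetic
        spec = PriorSpec(("p",), (BetaMarginal(3, 8),))
        assert log_prior(np.array([0.25]), spec) == pytest.approx(1.0997, abs=1e-4)

    def test_outside_support_is_minus_inf(self):
        prior = default_prior()
        bad = c.load_truth().to_array().copy()
        bad[0] = 1.5  # padeno outside (0,1)
        assert log_prior(bad, prior) == -np.inf

    def test_mode_beats_tail(self):
        prior = default_prior()
        mode = c.load_truth().to_array()
        tail = mode.copy()
        tail[2] *= 100  # l far in the tail
        assert log_prior(mode, prior) > log_prior(tail, prior)

    def test_z_density_integrates_against_sampling(self):
        # transformed-scale density must match the sampled distribution
        prior = PriorSpec(("p", "r"), (BetaMarginal(3, 8),
                                       LognormalMarginal(-2.0, 0.5)))
        rng = np.random.default_rng(0)
        x = prior.sample(50_000, rng)
        z = prior.to_z(x)
        # compare sample moments with numerically integrated moments of p_z
        for j in range(2):
            grid = np.linspace(z[:, j].min() - 1, z[:, j].max() + 1, 4001)
            zz = np.zeros((grid.size, 2))
            zz[:, j] = grid
            zz[:, 1 - j] = np.median(z[:, 1 - j])
            # evaluate the marginal by transforming back per-coordinate
            m = prior.marginals[j]
            dens = np.exp(m.logpdf(m.from_z(grid)) + m.log_jacobian(grid))
            mean_num = np.trapezoid(grid * dens, grid)
            assert mean_num == pytest.approx(z[:, j].mean(), abs=0.02)


class TestLikelihood:
    def test_perfect_fit_value(self, fixed, life_table, targets, truth):
        """phi == y with unit sigmas gives -0.5*log(2*pi) per cell."""
        ev = LikelihoodEvaluator(fixed, life_table, targets,
                                 phi_eval_size=None)
        phi, defined = ev.phi(truth)
        assert defined.all()
        df = targets.data.copy()
        df["mean"] = phi
        df["se"] = 1.0
        ts = c.TargetSet(df, n_reps=targets.n_reps)
        ll = c.log_likelihood(truth, fixed, life_table, ts)
        assert ll == pytest.approx(-0.91894 * len(df), abs=1e-3)

    def test_doubling_sigma_identity(self, fixed, life_table, targets, truth):
        """log L with 2*sigma = log L - T*ln2 + (3/8) * sum((r/sigma)^2)."""
        ev = LikelihoodEvaluator(fixed, life_table, targets, phi_eval_size=None)
        ll1 = ev(truth)
        phi, _ = ev.phi(truth)
        r2 = ((ev.y - phi) / ev.sigma) ** 2
        df = targets.data.copy()
        df["se"] = 2.0 * df["se"]
        ts2 = c.TargetSet(df, n_reps=targets.n_reps)
        ll2 = c.log_likelihood(truth, fixed, life_table, ts2)
        expected = ll1 - len(df) * np.log(2) + (3 / 8) * r2.sum()
        assert ll2 == pytest.approx(expected, rel=1e-9)

    def test_truth_beats_distorted_parameters(self, fixed, life_table,
                                              targets, truth):
        distorted = c.CalibratedParams(**{
            **{n: getattr(truth, n) for n in c.CalibratedParams.NAMES},
            "lambda3": truth.lambda3 * 10})
        ll_truth = c.log_likelihood(truth, fixed, life_table, targets)
        ll_bad = c.log_likelihood(distorted, fixed, life_table, targets)
        assert ll_truth > ll_bad

    def test_invalid_parameters_give_minus_inf(self, fixed, life_table, targets):
        ev = LikelihoodEvaluator(fixed, life_table, targets)
        assert ev(np.full(9, -1.0)) == -np.inf

    def test_evaluation_noise_marginalisation_widens_sigma(self, fixed,
                                                           life_table, targets):
        exact = LikelihoodEvaluator(fixed, life_table, targets,
                                    phi_eval_size=None)
        marg = LikelihoodEvaluator(fixed, life_table, targets,
                                   phi_eval_size=100_000)
        assert np.all(marg.sigma >= exact.sigma)
        inc = targets.data.target_type.str.startswith("inc").to_numpy()
        ratio = marg.sigma / exact.sigma
        # incidence cells come from 100k cohorts: variance doubles
        assert ratio[-inc.sum():] == pytest.approx(np.sqrt(2), abs=1e-6)


class TestESS:
    @pytest.mark.parametrize("w,expected", [
        (np.ones(17), 17.0),
        ([0.0, 0.0, 5.0], 1.0),
        ([0.5, 0.5, 0.0], 2.0),
    ])
    def test_values(self, w, expected):
        assert effective_sample_size(w) == pytest.approx(expected)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.zeros(4))


class TestIMIS:
    def test_conjugate_normal_posterior(self):
        """Prior N(0,1), likelihood N(y=1 | theta, 1): posterior N(0.5, 0.5)."""
        prior = PriorSpec(("theta",), (NormalMarginal(0.0, 1.0),))
        sample = run_imis(prior, lambda t: -0.5 * (1.0 - float(np.atleast_1d(t)[0]))**2,
                          n0=1000, b=100, ess_target=800, max_iters=50, seed=5)
        d = sample.resampled[:, 0]
        mc_se = np.sqrt(0.5 / sample.ess)
        assert d.mean() == pytest.approx(0.5, abs=3 * mc_se)
        assert d.var() == pytest.approx(0.5, abs=3 * np.sqrt(2) * 0.5 / np.sqrt(sample.ess))
        mp = map_estimate(sample)
        assert abs(float(mp[0]) - 0.5) < 2 * np.sqrt(0.5)

    def test_flat_likelihood_recovers_prior(self):
        prior = PriorSpec(("p",), (BetaMarginal(3.0, 8.0),))
        sample = run_imis(prior, lambda t: 0.0, n0=2000, b=200,
                          ess_target=1500, max_iters=20, seed=9, n_opt=0)
        d = sample.resampled[:, 0]
        ks = stats.kstest(d, stats.beta(3, 8).cdf).statistic
        assert ks < 0.05

    def test_weight_normalisation_and_ess_bounds(self):
        prior = PriorSpec(("theta",), (NormalMarginal(0.0, 2.0),))
        sample = run_imis(prior, lambda t: -0.5 * float(np.atleast_1d(t)[0])**2,
                          n0=500, b=50, ess_target=400, max_iters=10, seed=2)
        assert sample.weights.sum() == pytest.approx(1.0)
        assert np.all(sample.weights >= 0)
        assert 1.0 <= sample.ess <= sample.draws.shape[0]

    def test_correlated_ridge_recovered(self):
        """A tight ridge theta1+theta2 ~= 1 yields corr ~ -1 and the right
        spread along the ridge."""
        prior = PriorSpec(("a", "b"), (NormalMarginal(0, 5), NormalMarginal(0, 5)))
        sample = run_imis(
            prior, lambda t: -0.5 * ((1.0 - float(np.sum(t))) / 0.1)**2,
            n0=1000, b=100, ess_target=800, max_iters=60, seed=6)
        d = sample.resampled
        assert np.corrcoef(d, rowvar=False)[0, 1] < -0.99
        s = d.sum(axis=1)
        assert s.mean() == pytest.approx(1.0, abs=0.05)
        assert s.std() == pytest.approx(0.1, rel=0.35)

    def test_impossible_likelihood_raises(self):
        prior = PriorSpec(("theta",), (NormalMarginal(0.0, 1.0),))
        with pytest.raises(RuntimeError):
            run_imis(prior, lambda t: -np.inf, n0=100, b=10, ess_target=50,
                     max_iters=2, seed=1, n_opt=0)


class TestSummaries:
    def _toy_sample(self, draws, logpost):
        n = draws.shape[0]
        w = np.full(n, 1.0 / n) if n else np.empty(0)
        return PosteriorSample(
            names=tuple(f"p{i}" for i in range(draws.shape[1])),
            draws=draws, z=draws, log_prior=logpost,
            log_lik=np.zeros(n), weights=w, ess=float(max(n, 1)),
            n_iterations=0, resample_idx=np.arange(n))

    def test_map_is_argmax_with_first_tie(self):
        draws = np.array([[0.0], [1.0], [2.0], [3.0]])
        s = self._toy_sample(draws, np.array([0.0, 5.0, 5.0, 1.0]))
        assert float(map_estimate(s)[0]) == 1.0

    def test_map_empty_sample_errors(self):
        s = self._toy_sample(np.empty((0, 1)), np.empty(0))
        with pytest.raises(ValueError):
            map_estimate(s)

    def test_constant_draws_collapse(self):
        draws = np.ones((50, 2))
        s = self._toy_sample(draws, np.zeros(50))
        summ = posterior_summary(s)
        assert (summ.table["sd"] == 0).all()
        assert (summ.table["lb"] == summ.table["ub"]).all()

    def test_known_bivariate_normal_correlation(self):
        rng = np.random.default_rng(44)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        draws = rng.multivariate_normal([0, 0], cov, size=5000)
        s = self._toy_sample(draws, np.zeros(5000))
        summ = posterior_summary(s)
        assert summ.corr("p0", "p1") == pytest.approx(0.8, abs=0.03)
        assert summ.correlation.to_numpy().diagonal() == pytest.approx(1.0)

    def test_degenerate_predictive_interval(self, fixed, life_table, truth):
        draws = np.tile(truth.to_array(), (20, 1))
        s = PosteriorSample(names=tuple(c.CalibratedParams.NAMES), draws=draws,
                            z=draws, log_prior=np.zeros(20),
                            log_lik=np.zeros(20), weights=np.full(20, 0.05),
                            ess=20.0, n_iterations=0,
                            resample_idx=np.arange(20))
        pp = posterior_predictive(s, fixed, life_table, c.DEFAULT_BINS)
        assert np.allclose(pp["pi_lo"], pp["pi_hi"])
        assert np.all((pp["pred_mean"] >= pp["pi_lo"] - 1e-12)
                      & (pp["pred_mean"] <= pp["pi_hi"] + 1e-12))
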