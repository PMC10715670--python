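"""Likelihood, IFM fitting, cross-validated goodness of fit, bootstrap, significance."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from pairrog import (ContrastTuning, bootstrap_rho_ci, classify_significance,
                     fit_independent, fit_pair, goodness_of_fit,
                     independent_rog_fitter, model_moments,
                     negative_log_likelihood, pairwise_rog_fitter)
from pairrog.dataset import PairObservations
from pairrog.experiments import _simulate_observations
from pairrog.fit import GofResult, cv_splits, nll_from_moments


@pytest.fixture(scope="module")
def obs500(simple_tuning_module):
    rng = np.random.default_rng(7)
    return _simulate_observations(simple_tuning_module, (6.25, 12.5, 25, 50, 100),
                                  500, rng)


@pytest.fixture(scope="module")
def simple_tuning_module():
    from pairrog import MarginalTuning
    n1 = MarginalTuning(r_max=30.0, epsilon=20.0, alpha_n=0.5, beta_n=1.3,
                        alpha_d=0.3, beta_d=1.2, r0=0.0, sigma_eta=0.0)
    n2 = MarginalTuning(r_max=45.0, epsilon=35.0, alpha_n=0.4, beta_n=1.5,
                        alpha_d=0.5, beta_d=1.1, r0=0.0, sigma_eta=0.0)
    return ContrastTuning(neuron1=n1, neuron2=n2, rho_n=0.3, rho_d=0.4)


class TestNegativeLogLikelihood:
    def test_equals_per_trial_gaussian_sum_up_to_constant(self, simple_tuning_module):
        # matrix form == sum of per-trial bivariate Gaussian neg log densities
        # minus the parameter-independent constant S*T*log(2*pi)
        rng = np.random.default_rng(1)
        obs = _simulate_observations(simple_tuning_module, (12.5, 50.0), 30, rng)
        tun = simple_tuning_module
        nll = negative_log_likelihood(obs, tun)
        means, covs = model_moments(tun, obs.contrasts)
        direct = 0.0
        for s in range(obs.n_conditions):
            mvn = multivariate_normal(means[s], covs[s])
            direct += -mvn.logpdf(obs.responses[s]).sum()
        const = sum(obs.counts) * np.log(2 * np.pi)
        assert nll == pytest.approx(direct - const, rel=1e-10)

    def test_empirical_moments_give_closed_form_value(self, obs500):
        # model == empirical moments: trace term = dimension, quadratic = 0
        emp_means, emp_covs = obs500.empirical_moments()
        nll = nll_from_moments(obs500.counts.astype(float), emp_means, emp_covs,
                               emp_means, emp_covs)
        expect = sum(
            0.5 * t * (np.log(np.linalg.det(c)) + 2.0)
            for t, c in zip(obs500.counts, emp_covs))
        assert nll == pytest.approx(expect, rel=1e-12)

    def test_mean_perturbation_increases_nll(self, obs500):
        emp_means, emp_covs = obs500.empirical_moments()
        base = nll_from_moments(obs500.counts.astype(float), emp_means, emp_covs,
                                emp_means, emp_covs)
        bumped = emp_means.copy()
        bumped[0, 0] += 1.0
        worse = nll_from_moments(obs500.counts.astype(float), emp_means, emp_covs,
                                 bumped, emp_covs)
        assert worse > base

    def test_singular_model_covariance_penalized_not_raised(self, obs500):
        emp_means, emp_covs = obs500.empirical_moments()
        bad = emp_covs.copy()
        bad[:, 0, 1] = bad[:, 1, 0] = np.sqrt(bad[:, 0, 0] * bad[:, 1, 1]) * 1.01
        val = nll_from_moments(obs500.counts.astype(float), emp_means, emp_covs,
                               emp_means, bad)
        assert np.isfinite(val) and val > 1e10


class TestFitIndependent:
    def test_recovers_mean_parameters_from_clean_data(self, simple_tuning_module):
        # tiny variability: the contrast-response parameters are pinned down
        from pairrog import MarginalTuning, build_pair_params, sample_trials
        clean = MarginalTuning(r_max=30.0, epsilon=20.0, alpha_n=1e-4, beta_n=1.0,
                               alpha_d=1e-6, beta_d=1.0, r0=0.0, sigma_eta=0.0)
        tun = ContrastTuning(neuron1=clean, neuron2=clean)
        rng = np.random.default_rng(2)
        obs = _simulate_observations(tun, (3.0, 6.25, 12.5, 25, 50, 100), 200, rng)
        fit = fit_independent(obs, 0, seed=0)
        assert fit.params.r_max == pytest.approx(30.0, rel=0.02)
        assert fit.params.epsilon == pytest.approx(20.0, rel=0.05)
        assert abs(fit.params.r0) < 0.3

    def test_variance_curve_recovered_at_large_t(self, obs500, simple_tuning_module):
        fit = fit_independent(obs500, 0, seed=0)
        emp_means, emp_covs = obs500.empirical_moments()
        means, covs = model_moments(
            ContrastTuning(neuron1=fit.params, neuron2=fit.params), obs500.contrasts)
        np.testing.assert_allclose(covs[:, 0, 0], emp_covs[:, 0, 0], rtol=0.2)

    def test_single_condition_flagged_underdetermined(self):
        rng = np.random.default_rng(0)
        resp = [rng.normal(10.0, 1.0, size=(30, 2))]
        obs = PairObservations(0, np.array([50.0]), np.array([30]), resp)
        fit = fit_independent(obs, 0, seed=0)
        assert fit.underdetermined


class TestFitPair:
    def test_marginals_unchanged_by_coupling_step(self, obs500):
        m1 = fit_independent(obs500, 0, seed=0)
        m2 = fit_independent(obs500, 1, seed=1)
        res = fit_pair(obs500, seed=0, fix_rho_eta=True)
        assert res.tuning.neuron1.as_array() == pytest.approx(m1.params.as_array())
        assert res.tuning.neuron2.as_array() == pytest.approx(m2.params.as_array())

    def test_coupling_step_does_not_worsen_nll(self, obs500):
        res = fit_pair(obs500, seed=0, fix_rho_eta=True)
        zero = ContrastTuning(neuron1=res.tuning.neuron1, neuron2=res.tuning.neuron2,
                              rho_n=0.0, rho_d=0.0)
        assert res.nll <= negative_log_likelihood(obs500, zero) + 1e-6

    def test_null_coupling_recovered_on_average(self):
        from pairrog import generate_parameter_grid
        grid = generate_parameter_grid("fig2", 6, seed=3, rho=(0.0, 0.0))
        fitted = []
        for i, tun in enumerate(grid.draws):
            obs = _simulate_observations(tun, (6.25, 25, 100), 300,
                                         np.random.default_rng(i))
            res = fit_pair(obs, seed=i, fix_rho_eta=True)
            fitted.append([res.tuning.rho_n, res.tuning.rho_d])
        fitted = np.array(fitted)
        assert abs(np.median(fitted)) < 0.25


class TestGoodnessOfFit:
    def test_oracle_model_scores_one(self, obs500):
        def oracle_fitter(train):
            tr_means, tr_covs = train.empirical_moments()
            idx = {c: i for i, c in enumerate(train.contrasts)}

            def predict(contrasts):
                sel = np.array([idx[c] for c in contrasts])
                return tr_means[sel], tr_covs[sel]
            return predict
        res = goodness_of_fit(obs500, oracle_fitter, cv=2, seed=0)
        assert res.score == pytest.approx(1.0, abs=1e-12)

    def test_null_model_scores_zero(self, obs500):
        def null_fitter(train):
            mean, cov = train.pooled_moments()

            def predict(contrasts):
                S = len(contrasts)
                return np.tile(mean, (S, 1)), np.tile(cov, (S, 1, 1))
            return predict
        res = goodness_of_fit(obs500, null_fitter, cv=2, seed=0)
        assert res.score == pytest.approx(0.0, abs=1e-12)

    def test_score_can_exceed_unity_under_cross_validation(self, obs500):
        # the fitted pairwise model pools information across folds and can
        # beat the oracle's fold-specific empirical moments on held-out data
        res = goodness_of_fit(obs500, pairwise_rog_fitter(seed=0), cv=2, seed=0)
        assert np.isfinite(res.score)
        assert res.score > 0.9  # near-perfect generative recovery

    def test_loo_default_for_small_trial_counts(self, simple_tuning_module):
        rng = np.random.default_rng(5)
        obs = _simulate_observations(simple_tuning_module, (12.5, 50.0), 8, rng)
        folds = cv_splits(obs, "loo", seed=0)
        assert len(folds) == 8
        for masks in folds:
            assert all(m.sum() == 1 for m in masks)


class TestBootstrapAndSignificance:
    def test_single_resample_gives_degenerate_interval(self, obs500):
        point = fit_pair(obs500, seed=0, fix_rho_eta=True)
        boot = bootstrap_rho_ci(obs500, n_boot=1, seed=0, point_fit=point)
        assert boot.ci_n[0] == boot.ci_n[1]
        assert boot.ci_d[0] == boot.ci_d[1]

    def test_interval_width_shrinks_with_more_trials(self, simple_tuning_module):
        widths = []
        for T in (60, 480):
            obs = _simulate_observations(simple_tuning_module, (6.25, 25, 100), T,
                                         np.random.default_rng(9))
            point = fit_pair(obs, seed=0, fix_rho_eta=True)
            boot = bootstrap_rho_ci(obs, n_boot=60, seed=1, point_fit=point,
                                    mode="full")
            widths.append(boot.ci_n[1] - boot.ci_n[0])
        assert widths[1] < widths[0]

    def test_classification_requires_both_criteria(self):
        class FakeBoot:
            significant_n = True
            significant_d = False
        flags = classify_significance(FakeBoot(), gof_pairwise=0.8, gof_independent=0.7)
        assert flags == {"rho_n": True, "rho_d": False, "pairwise_better": True}
        flags = classify_significance(FakeBoot(), gof_pairwise=0.6, gof_independent=0.7)
        assert flags["rho_n"] is False
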