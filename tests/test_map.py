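"""MAP inference of single-trial normalization: quartic system and solvers."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime, minimize_scalar

from pairrog import (PairParams, map_independent, neg_log_posterior,
                     quartic_coefficients, sample_trials, solve_map,
                     solve_map_numeric)
from pairrog.mapinf import _quartic_coeffs_poly, _solve_map_batch


@pytest.fixture
def trials(simple_pair):
    p = simple_pair
    # residual-free variant: the posterior is over D given R - mu_eta anyway
    return sample_trials(p, 40, 9)


class TestNegLogPosterior:
    def test_matches_density_product_oracle(self, simple_pair, rng):
        # -log [ p(N) p(D) |D1 D2| ] with N = (R - mu_eta) * D, up to a
        # constant independent of D
        from scipy.stats import multivariate_normal
        p = simple_pair
        R = np.array([49.0, 26.0])
        r = R - p.mu_eta
        pN = multivariate_normal(p.mu_N, p.cov_N)
        pD = multivariate_normal(p.mu_D, p.cov_D)

        def oracle(D):
            N = r * D
            return -(pN.logpdf(N) + pD.logpdf(D) + np.log(D[0] * D[1]))

        Ds = rng.uniform(0.5, 2.5, size=(12, 2))
        diffs = [neg_log_posterior(D, R, p) - oracle(D) for D in Ds]
        assert np.ptp(diffs) < 1e-9  # constant offset only

    def test_rejects_nonpositive_d(self, simple_pair):
        with pytest.raises(ValueError, match="positive"):
            neg_log_posterior([1.0, 0.0], [50.0, 25.0], simple_pair)

    def test_gradient_zero_at_map(self, simple_pair, trials):
        p = simple_pair
        for R in trials[:10]:
            est = solve_map(R, p)
            D = np.array([est.d1, est.d2])
            g = approx_fprime(D, lambda d: neg_log_posterior(d, R, p), 1e-7)
            assert np.linalg.norm(g) < 1e-3 * (1 + abs(est.neg_log_posterior))


class TestQuarticCoefficients:
    def test_structure_against_symbolic_derivation(self, simple_pair):
        # multiply each partial derivative of the negative log posterior by
        # 2 D_i and match polynomial coefficients numerically
        p = simple_pair
        R = np.array([52.0, 24.0])
        r = R - p.mu_eta
        q = quartic_coefficients(R, p)
        iSN = np.linalg.inv(p.cov_N)
        iSD = np.linalg.inv(p.cov_D)
        assert q.A1 == pytest.approx(r[0] ** 2 * iSN[0, 0] + iSD[0, 0])
        assert q.A2 == pytest.approx(r[1] ** 2 * iSN[1, 1] + iSD[1, 1])
        assert q.C == pytest.approx(2.0 * (r[0] * r[1] * iSN[0, 1] + iSD[0, 1]))

        # the stationarity equations must vanish at the numerical minimizer
        est = solve_map_numeric(R, p)
        D1, D2 = est.d1, est.d2
        eq1 = 2 * q.A1 * D1**2 + q.B1 * D1 + q.C * D1 * D2 - 2
        eq2 = 2 * q.A2 * D2**2 + q.B2 * D2 + q.C * D1 * D2 - 2
        assert abs(eq1) < 1e-5 and abs(eq2) < 1e-5

    def test_shared_c_and_symmetry(self):
        p = PairParams(mu_N=[40, 40], mu_D=[1.5, 1.5], sigma_N=[2, 2],
                       sigma_D=[0.1, 0.1], rho_N=0.3, rho_D=0.2)
        q = quartic_coefficients([41.0, 41.0], p)
        assert q.A1 == pytest.approx(q.A2)
        assert q.B1 == pytest.approx(q.B2)

    def test_diagonal_covariances_give_zero_c(self, simple_pair):
        p = simple_pair
        p0 = PairParams(mu_N=p.mu_N, mu_D=p.mu_D, sigma_N=p.sigma_N,
                        sigma_D=p.sigma_D, rho_N=0.0, rho_D=0.0)
        q = quartic_coefficients([49.0, 26.0], p0)
        assert q.C == 0.0

    def test_quartic_has_four_roots(self, simple_pair, trials):
        for R in trials[:10]:
            coeffs = _quartic_coeffs_poly(quartic_coefficients(R, simple_pair))
            assert coeffs[4] != 0.0
            roots = np.polynomial.polynomial.polyroots(coeffs)
            assert len(roots) == 4


class TestSolveMap:
    def test_agrees_with_numerical_minimization(self, simple_pair, trials):
        for R in trials:
            alg = solve_map(R, simple_pair)
            num = solve_map_numeric(R, simple_pair)
            assert abs(alg.d1 - num.d1) < 1e-6
            assert abs(alg.d2 - num.d2) < 1e-6

    def test_decouples_to_independent_estimator(self, simple_pair, trials):
        p = simple_pair
        p0 = PairParams(mu_N=p.mu_N, mu_D=p.mu_D, sigma_N=p.sigma_N,
                        sigma_D=p.sigma_D, rho_N=0.0, rho_D=0.0,
                        mu_eta=p.mu_eta, sigma_eta=p.sigma_eta)
        for R in trials[:10]:
            est = solve_map(R, p0)
            r = np.asarray(R) - p0.mu_eta
            d1 = map_independent(r[0], p0.mu_N[0], p0.sigma_N[0], p0.mu_D[0],
                                 p0.sigma_D[0])
            d2 = map_independent(r[1], p0.mu_N[1], p0.sigma_N[1], p0.mu_D[1],
                                 p0.sigma_D[1])
            assert est.d1 == pytest.approx(d1, abs=1e-12)
            assert est.d2 == pytest.approx(d2, abs=1e-12)

    def test_prior_limit_small_sigma_d(self, simple_pair):
        p = simple_pair
        tight = PairParams(mu_N=p.mu_N, mu_D=p.mu_D, sigma_N=p.sigma_N,
                           sigma_D=[1e-5, 1e-5], rho_N=p.rho_N, rho_D=0.0,
                           mu_eta=p.mu_eta)
        est = solve_map([60.0, 20.0], tight)
        np.testing.assert_allclose([est.d1, est.d2], p.mu_D, rtol=1e-3)

    def test_batch_matches_scalar(self, simple_pair, trials):
        d, nlp, solver = _solve_map_batch(trials, simple_pair)
        for t, R in enumerate(trials):
            est = solve_map(R, simple_pair)
            assert d[t, 0] == pytest.approx(est.d1, abs=1e-9)
            assert d[t, 1] == pytest.approx(est.d2, abs=1e-9)
            assert nlp[t] == pytest.approx(est.neg_log_posterior, abs=1e-8)


class TestMapIndependent:
    def test_unique_positive_root_any_response(self, rng):
        for r in rng.uniform(-50, 80, size=30):
            d = map_independent(r, 40.0, 3.0, 1.5, 0.1)
            assert d > 0
            # verify it is a root of the stated quadratic
            a = r**2 / 9.0 + 1.0 / 0.01
            b = -(r * 40.0 / 9.0 + 1.5 / 0.01)
            assert a * d**2 + b * d - 1 == pytest.approx(0.0, abs=1e-6 * a)

    def test_matches_scalar_optimization_oracle(self):
        mu_N, s_N, mu_D, s_D = 40.0, 3.0, 1.5, 0.1
        for r in (20.0, 26.7, 35.0):
            def nlp(d):
                return (0.5 * (r * d - mu_N) ** 2 / s_N**2
                        + 0.5 * (d - mu_D) ** 2 / s_D**2 - np.log(d))
            opt = minimize_scalar(nlp, bounds=(1e-6, 10.0), method="bounded",
                                  options={"xatol": 1e-12})
            assert map_independent(r, mu_N, s_N, mu_D, s_D) == pytest.approx(
                opt.x, abs=1e-6)

    def test_consistent_response_recovers_prior_mean(self):
        # r = mu_N / mu_D with tiny numerator noise pins D near mu_D
        d = map_independent(40.0 / 1.5, 40.0, 1e-4, 1.5, 0.2)
        assert d == pytest.approx(1.5, rel=1e-3)


def test_estimate_dataset_empty_and_roundtrip(simple_tuning):
    import pandas as pd
    from pairrog import Dataset, estimate_dataset, generate_dataset, generate_parameter_grid
    empty = pd.DataFrame(columns=["pair_id", "stimulus", "trial", "r1", "r2"])
    out = estimate_dataset(Dataset(empty), {})
    assert len(out) == 0

    grid = generate_parameter_grid("fig4", 2, seed=3)
    ds, truth = generate_dataset(grid, contrasts=[25.0, 100.0], T=10, seed=5,
                                 record_latents=True)
    table = estimate_dataset(ds, {pid: grid.draws[pid] for pid in (0, 1)})
    assert len(table) == 2 * 2 * 10
    assert set(table.solver) <= {"algebraic", "algebraic-realpart", "numeric-fallback"}
    assert (table[["d1", "d2"]] > 0).all().all()
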