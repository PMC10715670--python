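"""Closed-form moment approximation: exact limits, decomposition, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairrog import (GeneralJointParams, PairParams, ValidityWarning,
                     approx_moments, approx_moments_general, corr_decomposition,
                     sample_trials, stimulus_dependent_parameters,
                     stimulus_independent_parameters)


def test_deterministic_limit_gives_exact_ratio_means():
    p = PairParams(mu_N=[50, 20], mu_D=[1, 2], sigma_N=[0, 0], sigma_D=[0, 0])
    m = approx_moments(p)
    np.testing.assert_allclose(m.mu_R, [50.0, 10.0])
    np.testing.assert_allclose(m.var_R, [0.0, 0.0])
    assert m.cov_R == 0.0
    assert not m.corr_defined and m.corr_R == 0.0


def test_equal_cvs_average_the_coupling_correlations():
    # with delta_N = delta_D for both neurons and no residual noise,
    # corr_R = (rho_N + rho_D) / 2
    p = PairParams(mu_N=[10, 20], mu_D=[1, 2], sigma_N=[1, 2],
                   sigma_D=[0.1, 0.2], rho_N=0.4, rho_D=0.4)
    assert approx_moments(p).corr_R == pytest.approx(0.4, abs=1e-12)
    p2 = PairParams(mu_N=[10, 20], mu_D=[1, 2], sigma_N=[1, 2],
                    sigma_D=[0.1, 0.2], rho_N=0.6, rho_D=0.2)
    assert approx_moments(p2).corr_R == pytest.approx(0.4, abs=1e-12)


def test_rejects_nonpositive_denominator_mean():
    with pytest.raises(ValueError, match="mu_D"):
        PairParams(mu_N=[1, 1], mu_D=[0.0, 1.0], sigma_N=[1, 1], sigma_D=[0.1, 0.1])


def test_validity_warning_when_denominator_mass_near_zero():
    p = PairParams(mu_N=[10, 10], mu_D=[1, 1], sigma_N=[1, 1], sigma_D=[0.5, 0.1])
    with pytest.warns(ValidityWarning):
        approx_moments(p)


def _random_params(rng, with_eta=True):
    return PairParams(
        mu_N=rng.uniform(1, 100, 2), mu_D=rng.uniform(0.5, 3.0, 2),
        sigma_N=rng.uniform(0.1, 5.0, 2), sigma_D=rng.uniform(0.01, 0.1, 2),
        rho_N=rng.uniform(-0.9, 0.9), rho_D=rng.uniform(-0.9, 0.9),
        mu_eta=rng.uniform(-1, 1, 2) if with_eta else np.zeros(2),
        sigma_eta=rng.uniform(0, 1, 2) if with_eta else np.zeros(2),
        rho_eta=rng.uniform(-0.9, 0.9) if with_eta else 0.0,
    )


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=60, deadline=None)
def test_correlation_bounded_and_label_symmetric(seed):
    rng = np.random.default_rng(seed)
    p = _random_params(rng)
    m = approx_moments(p)
    assert abs(m.corr_R) <= 1.0
    assert m.cov_R**2 <= m.var_R[0] * m.var_R[1] + 1e-12
    ms = approx_moments(p.swapped())
    np.testing.assert_allclose(ms.mu_R, m.mu_R[::-1], rtol=1e-12)
    np.testing.assert_allclose(ms.var_R, m.var_R[::-1], rtol=1e-12)
    assert ms.cov_R == pytest.approx(m.cov_R, rel=1e-12)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=60, deadline=None)
def test_decomposition_sums_to_correlation(seed):
    rng = np.random.default_rng(seed)
    p = _random_params(rng)
    terms = corr_decomposition(p)
    assert sum(terms) == pytest.approx(approx_moments(p).corr_R, abs=1e-10)


def test_decomposition_matches_two_term_rearrangement():
    # first term of the eta-free rearrangement:
    # rho_N / sqrt((dD1^2/dN1^2 + 1)(dD2^2/dN2^2 + 1))
    p = PairParams(mu_N=[40, 25], mu_D=[1.5, 2.0], sigma_N=[2.0, 1.5],
                   sigma_D=[0.1, 0.08], rho_N=0.5, rho_D=0.0)
    dN = p.sigma_N / p.mu_N
    dD = p.sigma_D / p.mu_D
    expect = 0.5 / np.sqrt((dD[0]**2 / dN[0]**2 + 1) * (dD[1]**2 / dN[1]**2 + 1))
    term_N, term_D, term_eta = corr_decomposition(p)
    assert term_N == pytest.approx(expect, rel=1e-12)
    assert term_D == 0.0 and term_eta == 0.0


def test_decomposition_zero_couplings_give_zero_terms():
    p = PairParams(mu_N=[40, 25], mu_D=[1.5, 2.0], sigma_N=[2, 1.5],
                   sigma_D=[0.1, 0.08], rho_N=0.0, rho_D=0.0, rho_eta=0.0,
                   sigma_eta=[0.1, 0.1])
    assert corr_decomposition(p) == (0.0, 0.0, 0.0)


def test_decomposition_rejects_zero_variability():
    p = PairParams(mu_N=[40, 25], mu_D=[1.5, 2.0], sigma_N=[0, 0], sigma_D=[0, 0])
    with pytest.raises(ValueError, match="zero variability"):
        corr_decomposition(p)


def test_numerator_term_increases_with_normalization_strength():
    # holding everything else fixed, the shared-input contribution grows as
    # the mean normalization strengthens (its relative variability shrinks)
    base = dict(mu_N=[40.0, 25.0], sigma_N=[2.0, 1.5], sigma_D=[0.1, 0.08],
                rho_N=0.5, rho_D=0.0)
    mu_ds = np.linspace(1.0, 5.0, 12)
    terms = [corr_decomposition(PairParams(mu_D=[m, m], **base))[0] for m in mu_ds]
    assert np.all(np.diff(terms) > 0)


def test_correlation_monotone_in_mu_d_given_single_source():
    # shared input only -> increasing; shared normalization only -> decreasing
    rng = np.random.default_rng(0)
    for _ in range(20):
        sig_N = rng.uniform(0.5, 5.0, 2)
        sig_D = rng.uniform(0.01, 0.2, 2)
        mu_N = rng.uniform(5, 100, 2)
        mu_ds = np.linspace(1.0, 6.0, 9)

        up = [approx_moments(PairParams(mu_N=mu_N, mu_D=[m, m], sigma_N=sig_N,
                                        sigma_D=sig_D, rho_N=0.5, rho_D=0.0)).corr_R
              for m in mu_ds]
        down = [approx_moments(PairParams(mu_N=mu_N, mu_D=[m, m], sigma_N=sig_N,
                                          sigma_D=sig_D, rho_N=0.0, rho_D=0.5)).corr_R
                for m in mu_ds]
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)


def test_general_model_reduces_to_block_diagonal_case(simple_pair):
    g = GeneralJointParams.from_pair_params(simple_pair)
    m_g = approx_moments_general(g)
    m = approx_moments(simple_pair)
    np.testing.assert_allclose(m_g.mu_R, m.mu_R, rtol=1e-12)
    np.testing.assert_allclose(m_g.var_R, m.var_R, rtol=1e-12)
    assert m_g.cov_R == pytest.approx(m.cov_R, rel=1e-12)


def test_general_model_numerator_denominator_cross_term(simple_pair):
    # nonzero Cov(N1, D1) contributes -2 (mu_N1/mu_D1^3) Cov(N1, D1) to var_R1
    g = GeneralJointParams.from_pair_params(simple_pair)
    base = approx_moments_general(g)
    c = 0.02
    cov4 = g.cov4.copy()
    cov4[0, 2] = cov4[2, 0] = c
    g2 = GeneralJointParams(mean4=g.mean4, cov4=cov4, mu_eta=g.mu_eta,
                            sigma_eta=g.sigma_eta, rho_eta=g.rho_eta)
    m2 = approx_moments_general(g2)
    extra = -2.0 * simple_pair.mu_N[0] / simple_pair.mu_D[0] ** 3 * c
    assert m2.var_R[0] - base.var_R[0] == pytest.approx(extra, rel=1e-9)
    assert m2.var_R[1] == pytest.approx(base.var_R[1], rel=1e-12)


def test_general_model_matches_monte_carlo():
    rng = np.random.default_rng(42)
    for _ in range(5):
        mean4 = np.concatenate([rng.uniform(10, 60, 2), rng.uniform(1.0, 2.0, 2)])
        A = rng.standard_normal((4, 4)) * np.array([2.0, 2.0, 0.05, 0.05])
        cov4 = A.T * 0  # build a PSD matrix with controlled scales
        cov4 = (A.T @ A) * 0.25
        g = GeneralJointParams(mean4=mean4, cov4=cov4)
        m = approx_moments_general(g)
        x = rng.multivariate_normal(mean4, cov4, size=400_000)
        R = x[:, :2] / x[:, 2:]
        emp_cov = np.cov(R.T, ddof=0)
        np.testing.assert_allclose(m.mu_R, R.mean(axis=0), rtol=0.02, atol=0.05)
        np.testing.assert_allclose(m.var_R, np.diag(emp_cov), rtol=0.1)
        assert m.cov_R == pytest.approx(emp_cov[0, 1], rel=0.15, abs=0.02)


def test_moments_match_sampling_oracle(simple_pair):
    m = approx_moments(simple_pair)
    R = sample_trials(simple_pair, 400_000, 7)
    emp_cov = np.cov(R.T, ddof=0)
    np.testing.assert_allclose(m.mu_R, R.mean(axis=0), rtol=0.01)
    np.testing.assert_allclose(m.var_R, np.diag(emp_cov), rtol=0.05)
    assert m.cov_R == pytest.approx(emp_cov[0, 1], rel=0.05)


def test_parameter_counts_of_unreduced_model():
    assert len(stimulus_dependent_parameters()) == 10
    assert len(stimulus_independent_parameters()) == 5


def test_pair_params_json_roundtrip(simple_pair):
    p2 = type(simple_pair).from_json(simple_pair.to_json())
    np.testing.assert_allclose(p2.mu_N, simple_pair.mu_N)
    np.testing.assert_allclose(p2.sigma_eta, simple_pair.sigma_eta)
    assert p2.rho_D == simple_pair.rho_D
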