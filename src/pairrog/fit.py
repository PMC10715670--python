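"""Maximum-likelihood fitting of the pairwise RoG with bootstrap inference.

Fitting follows the two-step "inference functions for marginals" (IFM)
scheme for Gaussian copulas: first each neuron's marginal contrast model is
fit by maximum likelihood (equivalent to the independent RoG), then the
coupling correlations (rho_N, rho_D and optionally rho_eta) are optimized with
the marginals frozen.  The objective is the moment-matching form of the
Gaussian negative log-likelihood,

    NLL = sum_s (T_s/2) [ log|Sigma(s)| + Tr(Sigma(s)^-1 Sigma_hat(s))
                          + (mu_hat(s) - mu(s))^T Sigma(s)^-1 (mu_hat(s) - mu(s)) ]

which equals the sum of per-trial bivariate Gaussian negative log-densities up
to a parameter-independent constant when the empirical moments use the ML
(ddof=0) convention.  Model quality is scored by a cross-validated pseudo-R^2
between a null model (no stimulus modulation) and an oracle (per-stimulus
empirical training moments); confidence intervals for the coupling
correlations come from a within-condition paired bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset import Dataset, PairObservations
from .tuning import ContrastTuning, MarginalTuning, build_pair_params
from .core import approx_moments

__all__ = [
    "FitResult",
    "MarginalFit",
    "BootstrapResult",
    "GofResult",
    "negative_log_likelihood",
    "model_moments",
    "fit_independent",
    "fit_pair",
    "goodness_of_fit",
    "bootstrap_rho_ci",
    "classify_significance",
    "pairwise_rog_fitter",
    "independent_rog_fitter",
    "cv_splits",
    "RHO_BOUND",
]

#: Open bound for the coupling correlations; keeps the model covariance
#: nonsingular while letting fits pile up near +/-1 (flagged as boundary hits).
RHO_BOUND = 0.999
_BOUNDARY_TOL = 1.5e-3
#: Finite penalty returned for singular/invalid model covariances so that
#: optimizers can recover rather than crash.
_PENALTY = 1e12


def _as_obs(data) -> PairObservations:
    if isinstance(data, PairObservations):
        return data
    if isinstance(data, Dataset):
        pids = data.pair_ids
        if len(pids) != 1:
            raise ValueError("Dataset holds multiple pairs; select one with .pair(pair_id)")
        return data.pair(pids[0])
    raise TypeError(f"expected Dataset or PairObservations, got {type(data)!r}")


# ---------------------------------------------------------------------------
# Model moments and the matrix-form NLL
# ---------------------------------------------------------------------------

def model_moments(tuning: ContrastTuning, contrasts) -> tuple[np.ndarray, np.ndarray]:
    """Model mean (S, 2) and covariance (S, 2, 2) at each contrast."""
    means, covs = [], []
    for c in np.asarray(contrasts, dtype=float):
        m = approx_moments(build_pair_params(tuning, c))
        means.append(m.mu_R)
        covs.append(m.cov_matrix)
    return np.stack(means), np.stack(covs)


def _nll_terms(counts, emp_means, emp_covs, mod_means, mod_v1, mod_v2, mod_cov):
    det = mod_v1 * mod_v2 - mod_cov**2
    bad = (mod_v1 <= 0) | (mod_v2 <= 0) | (det <= 0)
    if np.any(bad):
        violation = float(np.sum(np.maximum(0.0, -det[bad]) + 1.0))
        return _PENALTY * violation
    e1 = emp_means[:, 0] - mod_means[:, 0]
    e2 = emp_means[:, 1] - mod_means[:, 1]
    tr = (mod_v2 * emp_covs[:, 0, 0] + mod_v1 * emp_covs[:, 1, 1]
          - 2.0 * mod_cov * emp_covs[:, 0, 1]) / det
    quad = (mod_v2 * e1**2 - 2.0 * mod_cov * e1 * e2 + mod_v1 * e2**2) / det
    return float(np.sum(0.5 * counts * (np.log(det) + tr + quad)))


def nll_from_moments(counts, emp_means, emp_covs, mod_means, mod_covs) -> float:
    """Matrix-form Gaussian NLL given model and empirical per-condition moments."""
    return _nll_terms(np.asarray(counts, dtype=float), emp_means, emp_covs,
                      mod_means, mod_covs[:, 0, 0], mod_covs[:, 1, 1], mod_covs[:, 0, 1])


def negative_log_likelihood(data, tuning: ContrastTuning) -> float:
    """Eq-form pairwise NLL of a single pair's data under ``tuning``.

    Conditions are weighted by their own trial counts; a singular model
    covariance yields a large finite penalty rather than an exception.
    """
    obs = _as_obs(data)
    emp_means, emp_covs = obs.empirical_moments()
    mod_means, mod_covs = model_moments(tuning, obs.contrasts)
    return nll_from_moments(obs.counts, emp_means, emp_covs, mod_means, mod_covs)


# ---------------------------------------------------------------------------
# Marginal (independent RoG) fit
# ---------------------------------------------------------------------------

_MARGINAL_NAMES = ("r_max", "epsilon", "alpha_n", "beta_n", "alpha_d", "beta_d",
                   "r0", "sigma_eta")


try:  # pragma: no cover - exercised implicitly wherever fitting runs
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap


@_njit(cache=True)
def _marginal_nll_grad_core(theta, c2, w, mhat, vhat):  # pragma: no cover
    rmax, eps, a_n, b_n, a_d, b_d, r0, s_e = (
        theta[0], theta[1], theta[2], theta[3], theta[4], theta[5], theta[6],
        theta[7])
    S = c2.shape[0]
    f = 0.0
    grad = np.zeros(8)
    for s in range(S):
        muN = rmax * c2[s]
        muD = eps * eps + c2[s]
        m = muN / muD + r0
        if muN > 0.0:
            logN = np.log(muN)
            vN = a_n * np.exp(b_n * logN)
        else:
            logN = 0.0
            vN = 0.0
        vD = a_d * muD**b_d
        v = vN / muD**2 + muN**2 * vD / muD**4 + s_e * s_e
        e = mhat[s] - m
        f += w[s] * (np.log(v) + (vhat[s] + e * e) / v)
        dLdv = w[s] * (1.0 / v - (vhat[s] + e * e) / (v * v))
        dLdm = -2.0 * w[s] * e / v
        # r_max
        dm = c2[s] / muD
        if muN > 0.0:
            dvN = a_n * b_n * np.exp((b_n - 1.0) * logN)
        else:
            dvN = 0.0
        dv = dvN * c2[s] / muD**2 + 2.0 * muN * c2[s] * vD / muD**4
        grad[0] += dLdm * dm + dLdv * dv
        # epsilon
        dm = -muN * 2.0 * eps / muD**2
        dv = 2.0 * eps * (-2.0 * vN / muD**3
                          + muN**2 * a_d * (b_d - 4.0) * muD**(b_d - 5.0))
        grad[1] += dLdm * dm + dLdv * dv
        # alpha_n, beta_n
        if muN > 0.0:
            grad[2] += dLdv * np.exp(b_n * logN) / muD**2
            grad[3] += dLdv * vN * logN / muD**2
        # alpha_d, beta_d
        grad[4] += dLdv * muN**2 * muD**(b_d - 4.0)
        grad[5] += dLdv * muN**2 * vD * np.log(muD) / muD**4
        # r0, sigma_eta
        grad[6] += dLdm
        grad[7] += dLdv * 2.0 * s_e
    return f, grad


def _marginal_nll_grad(theta, c2, w, mhat, vhat):
    """Single-neuron NLL and analytic gradient (compiled core).

    ``c2`` is contrast squared per condition, ``w = T_s/2``; ``mhat``/``vhat``
    the empirical mean and ML variance per condition.
    """
    f, g = _marginal_nll_grad_core(np.asarray(theta, dtype=float), c2, w, mhat,
                                   vhat)
    return float(f), g


def _marginal_nll_grad_ref(theta, c2, w, mhat, vhat):
    """Pure-numpy reference implementation (used to validate the compiled core)."""
    rmax, eps, a_n, b_n, a_d, b_d, r0, s_e = theta
    muN = rmax * c2
    muD = eps**2 + c2
    m = muN / muD + r0
    pos = muN > 0
    logN = np.where(pos, np.log(np.where(pos, muN, 1.0)), 0.0)
    vN = np.where(pos, a_n * np.exp(b_n * logN), 0.0)
    vD = a_d * muD**b_d
    v = vN / muD**2 + muN**2 * vD / muD**4 + s_e**2
    e = mhat - m
    f = float(np.sum(w * (np.log(v) + (vhat + e**2) / v)))

    dLdv = w * (1.0 / v - (vhat + e**2) / v**2)
    dLdm = -2.0 * w * e / v

    dm = np.empty((8, len(c2)))
    dv = np.empty((8, len(c2)))
    # r_max
    dm[0] = c2 / muD
    dv[0] = np.where(pos, a_n * b_n * np.exp((b_n - 1.0) * logN), 0.0) * c2 / muD**2 \
        + 2.0 * muN * c2 * vD / muD**4
    # epsilon
    dm[1] = -muN * 2.0 * eps / muD**2
    dv[1] = 2.0 * eps * (-2.0 * vN / muD**3 + muN**2 * a_d * (b_d - 4.0) * muD**(b_d - 5.0))
    # alpha_n, beta_n
    dv[2] = np.where(pos, np.exp(b_n * logN), 0.0) / muD**2
    dv[3] = vN * logN / muD**2
    # alpha_d, beta_d
    dv[4] = muN**2 * muD**(b_d - 4.0)
    dv[5] = muN**2 * vD * np.log(muD) / muD**4
    # r0, sigma_eta
    dv[6] = 0.0
    dv[7] = 2.0 * s_e
    dm[2:] = 0.0
    dm[6] = 1.0

    grad = dm @ dLdm + dv @ dLdv
    return f, grad


def _marginal_bounds(mhat, vhat):
    top = max(1.0, float(np.max(mhat)))
    sd_top = max(1e-3, 10.0 * float(np.sqrt(np.max(vhat))))
    return [
        (1e-6, 10.0 * top),        # r_max
        (1e-2, 300.0),             # epsilon
        (1e-6, 1e3),               # alpha_n
        (0.25, 3.0),               # beta_n
        (1e-6, 1e3),               # alpha_d
        (0.25, 3.0),               # beta_d
        (-top, top),               # r0
        (0.0, sd_top),             # sigma_eta
    ]


#: Indices of marginal parameters optimized in log scale (r_max, epsilon,
#: alpha_n, alpha_d); the multiplicative geometry keeps L-BFGS well
#: conditioned across their orders of magnitude.
_LOG_IDX = np.array([0, 1, 2, 4])


def _to_psi(theta):
    psi = np.asarray(theta, dtype=float).copy()
    psi[_LOG_IDX] = np.log(np.maximum(psi[_LOG_IDX], 1e-300))
    return psi


def _from_psi(psi):
    theta = np.asarray(psi, dtype=float).copy()
    theta[_LOG_IDX] = np.exp(theta[_LOG_IDX])
    return theta


def _marginal_nll_grad_psi(psi, c2, w, mhat, vhat):
    theta = _from_psi(psi)
    f, g = _marginal_nll_grad(theta, c2, w, mhat, vhat)
    g[_LOG_IDX] = g[_LOG_IDX] * theta[_LOG_IDX]
    return f, g


def _variance_init(contrasts, mhat, vhat, rmax0, eps0):
    """Data-driven start for (alpha_n, beta_n, alpha_d, beta_d, sigma_eta)."""
    posm = mhat > 0
    if posm.sum() >= 2:
        slope, _ = np.polyfit(np.log(mhat[posm]), np.log(np.maximum(vhat[posm], 1e-12)), 1)
        beta0 = float(np.clip(slope, 0.25, 3.0))
    else:
        beta0 = 1.0
    hi = int(np.argmax(contrasts))
    muN_hi = rmax0 * contrasts[hi] ** 2
    muD_hi = eps0**2 + contrasts[hi] ** 2
    v_hi = max(float(vhat[hi]), 1e-8)
    alpha_n0 = float(np.clip(0.9 * v_hi * muD_hi**2 / max(muN_hi, 1e-6) ** beta0, 1e-6, 1e3))
    alpha_d0 = float(np.clip(0.1 * v_hi * muD_hi**4 / (max(muN_hi, 1e-6) ** 2 * muD_hi**beta0),
                             1e-6, 1e3))
    s_e0 = 0.05 * float(np.sqrt(np.median(vhat)))
    return np.array([alpha_n0, beta0, alpha_d0, beta0, s_e0])


def _marginal_init(contrasts, mhat, vhat, bounds):
    rmax0 = max(1e-3, float(np.max(mhat)))
    half = rmax0 / 2.0
    eps0 = float(np.clip(contrasts[np.argmin(np.abs(mhat - half))], 1.0, 300.0))
    var0 = _variance_init(contrasts, mhat, vhat, rmax0, eps0)
    x0 = np.array([rmax0, eps0, var0[0], var0[1], var0[2], var0[3], 0.0, var0[4]])
    lo = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])
    return np.clip(x0, lo, hi_b)


def _jitter(x0, bounds, rng):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x = x0.copy()
    for j in range(len(x)):
        if lo[j] >= 0 and x[j] > 0:
            x[j] = x[j] * np.exp(0.4 * rng.standard_normal())
        else:
            x[j] = x[j] + 0.2 * (hi[j] - lo[j]) * rng.standard_normal() * 0.25
    return np.clip(x, lo, hi)


@dataclass
class MarginalFit:
    """Fitted single-neuron (independent RoG) parameters and diagnostics."""

    params: MarginalTuning
    nll: float
    converged: bool
    n_restarts: int
    underdetermined: bool = False


def _fit_marginal_arrays(contrasts, counts, mhat, vhat, starts, bounds,
                         ftol: float = 1e-10):
    """Bounded fit of the marginal parameters from multiple starts.

    Optimization runs in a partially logarithmic parametrization; starts and
    the returned optimum are in natural (theta) scale.
    """
    best_f, best_x, any_conv = np.inf, None, False
    c2 = contrasts**2
    w = counts / 2.0
    psi_bounds = [(np.log(max(lo, 1e-300)), np.log(hi)) if j in _LOG_IDX else (lo, hi)
                  for j, (lo, hi) in enumerate(bounds)]
    lo = np.array([b[0] for b in psi_bounds])
    hi = np.array([b[1] for b in psi_bounds])
    for x0 in starts:
        psi0 = np.clip(_to_psi(x0), lo, hi)
        res = optimize.minimize(
            _marginal_nll_grad_psi, psi0, args=(c2, w, mhat, vhat),
            method="L-BFGS-B", jac=True, bounds=psi_bounds,
            options={"maxiter": 400, "ftol": ftol},
        )
        any_conv = any_conv or bool(res.success)
        if res.fun < best_f:
            best_f, best_x = res.fun, _from_psi(res.x)
    return best_f, best_x, any_conv


def fit_independent(data, neuron: int, seed: int = 0, n_restarts: int = 5,
                    starts=None) -> MarginalFit:
    """Maximum-likelihood fit of one neuron's marginal contrast model.

    ``neuron`` is 0 or 1.  Uses ``n_restarts`` seeded multiplicative-jitter
    restarts around a deterministic initialization (max response, half-max
    contrast, log-log variance regression).  ``starts`` overrides the start
    list entirely (used for warm-started bootstrap refits).
    """
    obs = _as_obs(data)
    emp_means, emp_covs = obs.empirical_moments()
    mhat = emp_means[:, neuron]
    vhat = emp_covs[:, neuron, neuron]
    bounds = _marginal_bounds(mhat, vhat)
    if starts is None:
        rng = np.random.default_rng(seed)
        x0 = _marginal_init(obs.contrasts, mhat, vhat, bounds)
        starts = [x0] + [_jitter(x0, bounds, rng) for _ in range(max(0, n_restarts - 1))]
    best_f, best_x, converged = _fit_marginal_arrays(
        obs.contrasts, obs.counts.astype(float), mhat, vhat, starts, bounds)
    x = np.asarray(best_x, dtype=float)
    x[2:6] = np.maximum(x[2:6], 1e-6)    # keep alpha/beta strictly positive
    x[1] = max(x[1], 1e-2)
    x[0] = max(x[0], 1e-6)
    return MarginalFit(
        params=MarginalTuning.from_array(x),
        nll=float(best_f),
        converged=bool(converged),
        n_restarts=len(starts),
        underdetermined=obs.n_conditions < 2,
    )


# ---------------------------------------------------------------------------
# Coupling (rho) step and the full pairwise fit
# ---------------------------------------------------------------------------

def _rho_coefficients(tuning: ContrastTuning, contrasts):
    """Per-condition model means, per-neuron variances and the coefficients of
    the covariance as a linear function of (rho_N, rho_D, rho_eta)."""
    S = len(contrasts)
    means = np.empty((S, 2))
    comp = np.empty((S, 3, 2))  # (condition, source, neuron) variance components
    for s, c in enumerate(np.asarray(contrasts, dtype=float)):
        p = build_pair_params(tuning, c)
        means[s] = p.mu_N / p.mu_D + p.mu_eta
        comp[s, 0] = p.sigma_N**2 / p.mu_D**2
        comp[s, 1] = p.mu_N**2 * p.sigma_D**2 / p.mu_D**4
        comp[s, 2] = p.sigma_eta**2
    variances = comp.sum(axis=1)
    k = np.sqrt(comp[:, :, 0] * comp[:, :, 1])  # (S, 3): cov coefficient per source
    return means, variances, k


def _fit_rho(counts, emp_means, emp_covs, mod_means, mod_vars, k, fix_rho_eta,
             starts):
    v1, v2 = mod_vars[:, 0], mod_vars[:, 1]
    e1 = emp_means[:, 0] - mod_means[:, 0]
    e2 = emp_means[:, 1] - mod_means[:, 1]
    vh1, vh2, ch = emp_covs[:, 0, 0], emp_covs[:, 1, 1], emp_covs[:, 0, 1]
    ndim = 2 if fix_rho_eta else 3
    kk = k[:, :ndim]

    def obj(rho):
        cov = kk @ rho
        det = v1 * v2 - cov**2
        if np.any(det <= 0):
            bad = det <= 0
            return _PENALTY * float(np.sum(np.maximum(0.0, -det[bad]) + 1.0)), \
                np.zeros(ndim)
        tr = (v2 * vh1 + v1 * vh2 - 2.0 * cov * ch) / det
        quad = (v2 * e1**2 - 2.0 * cov * e1 * e2 + v1 * e2**2) / det
        f = float(np.sum(0.5 * counts * (np.log(det) + tr + quad)))
        df_dc = counts * (-cov - ch - e1 * e2 + cov * (tr + quad)) / det
        return f, df_dc @ kk

    bounds = [(-RHO_BOUND, RHO_BOUND)] * ndim
    best = None
    for x0 in starts:
        res = optimize.minimize(obj, np.asarray(x0[:ndim], dtype=float),
                                method="L-BFGS-B", jac=True, bounds=bounds,
                                options={"maxiter": 300, "ftol": 1e-12,
                                         "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    rho = np.clip(best.x, -RHO_BOUND, RHO_BOUND)
    full = np.zeros(3)
    full[:ndim] = rho
    return full, float(best.fun)


def _rho_starts(obs: PairObservations):
    corrs = obs.noise_correlations()
    r = float(np.clip(np.median(corrs), -0.9, 0.9))
    return [np.array([r, r, 0.0]), np.array([r, 0.0, 0.0]),
            np.array([0.0, r, 0.0]), np.array([0.0, 0.0, 0.0])]


@dataclass
class FitResult:
    """Fitted pairwise model: tuning parameters, training NLL and diagnostics."""

    tuning: ContrastTuning
    nll: float
    gof: float | None = None
    fold_scores: list = field(default_factory=list)
    converged: bool = True
    n_restarts: int = 0
    boundary_rho: dict = field(default_factory=dict)
    marginal_fits: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "tuning": self.tuning.to_dict(),
            "nll": self.nll,
            "gof": self.gof,
            "fold_scores": list(self.fold_scores),
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "boundary_rho": dict(self.boundary_rho),
        }


def fit_pair(data, seed: int = 0, fix_rho_eta: bool = False, n_restarts: int = 5,
             marginals: tuple | None = None, rho_start=None) -> FitResult:
    """Two-step (IFM) maximum-likelihood fit of the pairwise RoG.

    Step 1 fits each neuron's marginal model independently; step 2 maximizes
    the pairwise likelihood over the coupling correlations with the marginals
    frozen.  ``fix_rho_eta`` pins rho_eta at 0 (appropriate for data without
    residual noise).  ``marginals``/``rho_start`` warm-start the two steps for
    bootstrap refits.  Fits with |rho| at the optimization bound are recorded
    in ``boundary_rho`` (the bound is 0.999, standing in for +/-1).
    """
    obs = _as_obs(data)
    if marginals is None:
        m1 = fit_independent(obs, 0, seed=seed, n_restarts=n_restarts)
        m2 = fit_independent(obs, 1, seed=seed + 1, n_restarts=n_restarts)
    else:
        m1, m2 = marginals
    tuning0 = ContrastTuning(neuron1=m1.params, neuron2=m2.params)
    emp_means, emp_covs = obs.empirical_moments()
    mod_means, mod_vars, k = _rho_coefficients(tuning0, obs.contrasts)
    starts = [np.asarray(rho_start, dtype=float)] if rho_start is not None \
        else _rho_starts(obs)
    rho, nll = _fit_rho(obs.counts.astype(float), emp_means, emp_covs,
                        mod_means, mod_vars, k, fix_rho_eta, starts)
    tuning = ContrastTuning(neuron1=m1.params, neuron2=m2.params,
                            rho_n=float(rho[0]), rho_d=float(rho[1]),
                            rho_eta=float(rho[2]))
    boundary = {name: bool(abs(val) >= RHO_BOUND - _BOUNDARY_TOL)
                for name, val in zip(("rho_n", "rho_d", "rho_eta"), rho)}
    return FitResult(
        tuning=tuning, nll=nll,
        converged=m1.converged and m2.converged,
        n_restarts=n_restarts, boundary_rho=boundary,
        marginal_fits=(m1, m2),
    )


# ---------------------------------------------------------------------------
# Cross-validated goodness of fit
# ---------------------------------------------------------------------------

def cv_splits(obs: PairObservations, scheme, seed: int = 0):
    """Per-condition trial splits.

    ``scheme``: ``"loo"`` for leave-one-out or an integer fold count; folds are
    stratified within condition with seeded shuffling.  Yields, per fold, a
    list of boolean test masks aligned with ``obs.responses``.
    """
    rng = np.random.default_rng(seed)
    if scheme == "loo":
        k = int(min(obs.counts))
        perms = [np.arange(n) for n in obs.counts]
    else:
        k = int(scheme)
        if k < 2:
            raise ValueError("fold count must be >= 2")
        if k > int(min(obs.counts)):
            raise ValueError("more folds than trials in the smallest condition")
        perms = [rng.permutation(n) for n in obs.counts]
    folds = []
    for j in range(k):
        masks = []
        for perm in perms:
            chunk = np.array_split(perm, k)[j]
            m = np.zeros(len(perm), dtype=bool)
            m[chunk] = True
            masks.append(m)
        folds.append(masks)
    return folds


def default_cv_scheme(obs: PairObservations):
    """Leave-one-out for small trial counts (T <= 20), else 10-fold."""
    return "loo" if int(min(obs.counts)) <= 20 else 10


@dataclass
class GofResult:
    score: float
    fold_scores: list
    degenerate: bool = False


def pairwise_rog_fitter(seed: int = 0, fix_rho_eta: bool = True, n_restarts: int = 3):
    """Fitter interface for :func:`goodness_of_fit` using the pairwise RoG."""
    def fit(train: PairObservations):
        res = fit_pair(train, seed=seed, fix_rho_eta=fix_rho_eta, n_restarts=n_restarts)

        def predict(contrasts):
            return model_moments(res.tuning, contrasts)
        return predict
    return fit


def independent_rog_fitter(seed: int = 0, n_restarts: int = 3):
    """Fitter for the independent RoG (pairwise model with zero coupling)."""
    def fit(train: PairObservations):
        m1 = fit_independent(train, 0, seed=seed, n_restarts=n_restarts)
        m2 = fit_independent(train, 1, seed=seed + 1, n_restarts=n_restarts)
        tuning = ContrastTuning(neuron1=m1.params, neuron2=m2.params)

        def predict(contrasts):
            return model_moments(tuning, contrasts)
        return predict
    return fit


def goodness_of_fit(data, fitter, cv=None, seed: int = 0) -> GofResult:
    """Cross-validated pseudo-R^2 of a model against null and oracle references.

    Per held-out split: score = (NLL_fit - NLL_null) / (NLL_oracle - NLL_null)
    where the null predicts the pooled training moments for every stimulus and
    the oracle predicts each stimulus's own empirical training moments.  The
    reported score is the median across splits; values may fall outside [0, 1]
    under cross-validation.  A split whose oracle coincides with its null is
    flagged degenerate and skipped.
    """
    obs = _as_obs(data)
    scheme = cv if cv is not None else default_cv_scheme(obs)
    fold_scores = []
    degenerate = False
    for masks in cv_splits(obs, scheme, seed=seed):
        train, test = obs.split(masks)
        predict = fitter(train)
        te_means, te_covs = test.empirical_moments()
        counts = test.counts.astype(float)

        mod_means, mod_covs = predict(test.contrasts)
        nll_fit = nll_from_moments(counts, te_means, te_covs, mod_means, mod_covs)

        tr_means, tr_covs = train.empirical_moments()
        tr_idx = {c: i for i, c in enumerate(train.contrasts)}
        sel = np.array([tr_idx[c] for c in test.contrasts])
        nll_oracle = nll_from_moments(counts, te_means, te_covs,
                                      tr_means[sel], tr_covs[sel])

        pool_mean, pool_cov = train.pooled_moments()
        S = len(test.contrasts)
        nll_null = nll_from_moments(counts, te_means, te_covs,
                                    np.tile(pool_mean, (S, 1)),
                                    np.tile(pool_cov, (S, 1, 1)))
        denom = nll_oracle - nll_null
        if denom == 0 or not np.isfinite(denom):
            degenerate = True
            continue
        fold_scores.append(float((nll_fit - nll_null) / denom))
    score = float(np.median(fold_scores)) if fold_scores else float("nan")
    return GofResult(score=score, fold_scores=fold_scores,
                     degenerate=degenerate or not fold_scores)


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals and significance
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap CIs for the coupling correlations."""

    n_boot: int
    rho_samples: pd.DataFrame
    ci_level: float
    ci_n: tuple
    ci_d: tuple
    significant_n: bool
    significant_d: bool
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
            "ci_n": list(self.ci_n),
            "ci_d": list(self.ci_d),
            "significant_n": self.significant_n,
            "significant_d": self.significant_d,
            "n_skipped": self.n_skipped,
        }


def bootstrap_rho_ci(data, n_boot: int, level: float = 0.9, seed: int = 0,
                     mode: str = "full", fix_rho_eta: bool = True,
                     point_fit: FitResult | None = None) -> BootstrapResult:
    """Within-condition paired bootstrap for (rho_N, rho_D).

    Each resample redraws trials with replacement within every stimulus
    condition (pairs kept together, per-condition counts preserved) and refits
    the pairwise model.  ``mode="full"`` refits marginals and coupling per
    resample (marginal refits warm-start at the point fit with a single
    restart); ``mode="rho-only"`` freezes the point-fit marginals.  CIs are
    percentile intervals; ``significant_*`` flags mark intervals excluding 0.
    Resamples with a degenerate condition covariance are skipped and counted.
    """
    if mode not in ("full", "rho-only"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    obs = _as_obs(data)
    rng = np.random.default_rng(seed)
    if point_fit is None:
        point_fit = fit_pair(obs, seed=seed, fix_rho_eta=fix_rho_eta)
    m1, m2 = point_fit.marginal_fits
    rho_pt = np.array([point_fit.tuning.rho_n, point_fit.tuning.rho_d,
                       point_fit.tuning.rho_eta])
    rows = []
    n_skipped = 0
    for _ in range(n_boot):
        rs = obs.resample(rng)
        emp_means, emp_covs = rs.empirical_moments()
        dets = emp_covs[:, 0, 0] * emp_covs[:, 1, 1] - emp_covs[:, 0, 1] ** 2
        if np.any(dets <= 0):
            n_skipped += 1
            continue
        if mode == "full":
            # Refit marginals with the same data-driven initialization the
            # point fit uses (plus the point fit as a warm start) so the
            # resampling distribution reflects marginal-fit variability —
            # essential for the CIs to attain their nominal coverage.
            margs = []
            for neuron in (0, 1):
                mhat = emp_means[:, neuron]
                vhat = emp_covs[:, neuron, neuron]
                bnds = _marginal_bounds(mhat, vhat)
                x0 = _marginal_init(rs.contrasts, mhat, vhat, bnds)
                starts = [x0]
                _, best_x, _ = _fit_marginal_arrays(
                    rs.contrasts, rs.counts.astype(float), mhat, vhat, starts,
                    bnds, ftol=1e-9)
                x = np.asarray(best_x, dtype=float)
                x[2:6] = np.maximum(x[2:6], 1e-6)
                x[1] = max(x[1], 1e-2)
                x[0] = max(x[0], 1e-6)
                margs.append(MarginalTuning.from_array(x))
            tuning0 = ContrastTuning(neuron1=margs[0], neuron2=margs[1])
        else:
            tuning0 = ContrastTuning(neuron1=m1.params, neuron2=m2.params)
        mod_means, mod_vars, k = _rho_coefficients(tuning0, rs.contrasts)
        sd = np.sqrt(emp_covs[:, 0, 0] * emp_covs[:, 1, 1])
        r_emp = float(np.clip(np.median(emp_covs[:, 0, 1] / sd), -0.9, 0.9))
        starts = [np.array([r_emp, r_emp, 0.0]), np.zeros(3), rho_pt]
        rho, _ = _fit_rho(rs.counts.astype(float), emp_means, emp_covs,
                          mod_means, mod_vars, k, fix_rho_eta, starts)
        rows.append(rho)
    samples = pd.DataFrame(rows, columns=["rho_n", "rho_d", "rho_eta"])
    qlo, qhi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    if len(samples):
        ci_n = tuple(np.quantile(samples["rho_n"], [qlo, qhi]))
        ci_d = tuple(np.quantile(samples["rho_d"], [qlo, qhi]))
    else:
        ci_n = ci_d = (float("nan"), float("nan"))
    return BootstrapResult(
        n_boot=n_boot, rho_samples=samples, ci_level=level,
        ci_n=ci_n, ci_d=ci_d,
        significant_n=bool(len(samples) and (ci_n[0] > 0 or ci_n[1] < 0)),
        significant_d=bool(len(samples) and (ci_d[0] > 0 or ci_d[1] < 0)),
        n_skipped=n_skipped,
    )


def classify_significance(boot: BootstrapResult, gof_pairwise: float,
                          gof_independent: float) -> dict:
    """A coupling correlation counts as significant when its CI excludes 0 AND
    the pairwise cross-validated goodness of fit beats the independent one."""
    better = bool(gof_pairwise > gof_independent)
    return {
        "rho_n": bool(boot.significant_n and better),
        "rho_d": bool(boot.significant_d and better),
        "pairwise_better": better,
    }
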