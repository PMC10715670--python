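"""Modulated-Gaussian (MG) comparison model.

A Gaussianized variant of the modulated-Poisson model: responses are bivariate
Gaussian whose moments inherit the compound Poisson-Gamma structure — the mean
follows the contrast-response function, the variance is
mean + gain-variance * mean^2 (+ residual), and the covariance combines a
point-process-like term (rho_P), a shared multiplicative-gain term (rho_G) and
the residual term (rho_eta).  With zero gain SD and zero residual the variance
equals the mean (Poisson-like dispersion), so without residual noise the model
can only be overdispersed (Fano factor >= 1), unlike the RoG.

The covariance's first term is implemented in the form
``rho_P * mu_R1 * mu_R2`` (a documented alternative uses
``rho_P * sqrt(mu_R1 * mu_R2)``, the scaling a shared Poisson point process
would produce; see ``sqrt_point_term``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize

from .core import MomentSet, _check_rho, _finish_moments
from .fit import (FitResult, PairObservations, _as_obs, _nll_terms,
                  RHO_BOUND, _BOUNDARY_TOL, goodness_of_fit)

__all__ = ["MGMarginal", "MGParams", "mg_moments", "fit_mg", "mg_fitter"]


@dataclass
class MGMarginal:
    """Per-neuron MG parameters: contrast tuning plus gain and residual SDs."""

    r_max: float
    epsilon: float
    mu_eta: float = 0.0
    sigma_g: float = 0.0
    sigma_eta: float = 0.0

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.epsilon <= 0:
            raise ValueError("r_max and epsilon must be > 0")
        if self.sigma_g < 0 or self.sigma_eta < 0:
            raise ValueError("sigma_g and sigma_eta must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_max, self.epsilon, self.mu_eta, self.sigma_g,
                         self.sigma_eta])

    @classmethod
    def from_array(cls, x) -> "MGMarginal":
        return cls(*[float(v) for v in x])


@dataclass
class MGParams:
    """Pairwise modulated-Gaussian specification."""

    neuron1: MGMarginal
    neuron2: MGMarginal
    rho_p: float = 0.0
    rho_g: float = 0.0
    rho_eta: float = 0.0
    sqrt_point_term: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.neuron1, dict):
            self.neuron1 = MGMarginal(**self.neuron1)
        if isinstance(self.neuron2, dict):
            self.neuron2 = MGMarginal(**self.neuron2)
        self.rho_p = _check_rho(self.rho_p, "rho_p")
        self.rho_g = _check_rho(self.rho_g, "rho_g")
        self.rho_eta = _check_rho(self.rho_eta, "rho_eta")

    @property
    def neurons(self):
        return (self.neuron1, self.neuron2)

    def to_dict(self) -> dict:
        return {
            "neuron1": asdict(self.neuron1), "neuron2": asdict(self.neuron2),
            "rho_p": self.rho_p, "rho_g": self.rho_g, "rho_eta": self.rho_eta,
            "sqrt_point_term": self.sqrt_point_term,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "MGParams":
        return cls(**d)


def _mg_marginal_moments(m: MGMarginal, c: float):
    mu = m.r_max * c**2 / (m.epsilon**2 + c**2) + m.mu_eta
    var = mu + m.sigma_g**2 * mu**2 + m.sigma_eta**2
    return mu, var


def mg_moments(params: MGParams, c: float) -> MomentSet:
    """MG model moments at contrast ``c`` (percent)."""
    if c < 0:
        raise ValueError(f"contrast must be non-negative, got {c}")
    mu = np.empty(2)
    var = np.empty(2)
    for i, m in enumerate(params.neurons):
        mu[i], var[i] = _mg_marginal_moments(m, c)
    point = np.sqrt(mu[0] * mu[1]) if params.sqrt_point_term else mu[0] * mu[1]
    cov = (params.rho_p * point
           + params.rho_g * params.neuron1.sigma_g * params.neuron2.sigma_g * mu[0] * mu[1]
           + params.rho_eta * params.neuron1.sigma_eta * params.neuron2.sigma_eta)
    return _finish_moments(mu, var, cov)


def mg_model_moments(params: MGParams, contrasts):
    """Mean (S, 2) and covariance (S, 2, 2) across a contrast set."""
    means, covs = [], []
    for c in np.asarray(contrasts, dtype=float):
        m = mg_moments(params, c)
        means.append(m.mu_R)
        covs.append(m.cov_matrix)
    return np.stack(means), np.stack(covs)


# ---------------------------------------------------------------------------
# Fitting (same two-step IFM scheme and Eq-11/Eq-12 machinery as the RoG)
# ---------------------------------------------------------------------------

def _mg_marginal_nll(theta, c, w, mhat, vhat):
    m = MGMarginal.from_array(np.maximum(theta, [1e-6, 1e-2, theta[2], 0.0, 0.0]))
    mu = m.r_max * c**2 / (m.epsilon**2 + c**2) + m.mu_eta
    var = mu + m.sigma_g**2 * mu**2 + m.sigma_eta**2
    if np.any(var <= 0):
        return 1e12 * (1.0 + float(np.sum(np.maximum(0.0, -var))))
    e = mhat - mu
    return float(np.sum(w * (np.log(var) + (vhat + e**2) / var)))


def _fit_mg_marginal(obs: PairObservations, neuron: int, seed: int,
                     n_restarts: int) -> MGMarginal:
    emp_means, emp_covs = obs.empirical_moments()
    mhat = emp_means[:, neuron]
    vhat = emp_covs[:, neuron, neuron]
    c = obs.contrasts
    w = obs.counts.astype(float) / 2.0
    top = max(1.0, float(np.max(mhat)))
    bounds = [(1e-6, 10.0 * top), (1e-2, 300.0), (-top, top),
              (0.0, 10.0), (0.0, 10.0 * max(1e-3, float(np.sqrt(vhat.max()))))]
    rmax0 = max(1e-3, float(np.max(mhat)))
    eps0 = float(np.clip(c[np.argmin(np.abs(mhat - rmax0 / 2.0))], 1.0, 300.0))
    sg0 = 0.3
    x0 = np.clip(np.array([rmax0, eps0, 0.0, sg0, 0.05 * np.sqrt(max(vhat.mean(), 1e-8))]),
                 [b[0] for b in bounds], [b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        j = x0 * np.exp(0.4 * rng.standard_normal(5))
        j[2] = x0[2] + 0.1 * top * rng.standard_normal()
        starts.append(np.clip(j, [b[0] for b in bounds], [b[1] for b in bounds]))
    best = None
    for s in starts:
        res = optimize.minimize(_mg_marginal_nll, s, args=(c, w, mhat, vhat),
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return MGMarginal.from_array(best.x)


def fit_mg(data, seed: int = 0, fix_rho_eta: bool = True, n_restarts: int = 5,
           sqrt_point_term: bool = False) -> FitResult:
    """Two-step fit of the modulated Gaussian with the shared NLL machinery.

    Contracts mirror :func:`pairrog.fit.fit_pair`: marginals first, then the
    correlation parameters (rho_P, rho_G and optionally rho_eta) with
    marginals frozen, under the same matrix-form likelihood.  Returns a
    :class:`FitResult` whose ``tuning`` field holds :class:`MGParams`.
    """
    obs = _as_obs(data)
    m1 = _fit_mg_marginal(obs, 0, seed, n_restarts)
    m2 = _fit_mg_marginal(obs, 1, seed + 1, n_restarts)
    emp_means, emp_covs = obs.empirical_moments()
    counts = obs.counts.astype(float)

    mus = np.empty((obs.n_conditions, 2))
    vars_ = np.empty((obs.n_conditions, 2))
    for s, c in enumerate(obs.contrasts):
        for i, m in enumerate((m1, m2)):
            mus[s, i], vars_[s, i] = _mg_marginal_moments(m, c)
    prod = mus[:, 0] * mus[:, 1]
    k_p = np.sqrt(np.maximum(prod, 0.0)) if sqrt_point_term else prod
    k_g = m1.sigma_g * m2.sigma_g * prod
    k_e = np.full(obs.n_conditions, m1.sigma_eta * m2.sigma_eta)

    ndim = 2 if fix_rho_eta else 3

    def obj(rho):
        cov = rho[0] * k_p + rho[1] * k_g + (0.0 if ndim == 2 else rho[2]) * k_e
        return _nll_terms(counts, emp_means, emp_covs, mus, vars_[:, 0], vars_[:, 1], cov)

    best = None
    for x0 in ([0.0] * ndim, [0.1] * ndim, [-0.1] * ndim, [0.3, 0.0, 0.0][:ndim]):
        res = optimize.minimize(obj, np.asarray(x0, dtype=float), method="L-BFGS-B",
                                bounds=[(-RHO_BOUND, RHO_BOUND)] * ndim,
                                options={"maxiter": 300, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    rho = np.zeros(3)
    rho[:ndim] = np.clip(best.x, -RHO_BOUND, RHO_BOUND)
    params = MGParams(neuron1=m1, neuron2=m2, rho_p=float(rho[0]),
                      rho_g=float(rho[1]), rho_eta=float(rho[2]),
                      sqrt_point_term=sqrt_point_term)
    boundary = {name: bool(abs(val) >= RHO_BOUND - _BOUNDARY_TOL)
                for name, val in zip(("rho_p", "rho_g", "rho_eta"), rho)}
    return FitResult(tuning=params, nll=float(best.fun), n_restarts=n_restarts,
                     boundary_rho=boundary)


def mg_fitter(seed: int = 0, fix_rho_eta: bool = True, n_restarts: int = 3,
              sqrt_point_term: bool = False):
    """Fitter interface for :func:`pairrog.fit.goodness_of_fit`."""
    def fit(train: PairObservations):
        res = fit_mg(train, seed=seed, fix_rho_eta=fix_rho_eta,
                     n_restarts=n_restarts, sqrt_point_term=sqrt_point_term)

        def predict(contrasts):
            return mg_model_moments(res.tuning, contrasts)
        return predict
    return fit


def compare_gof(data, cv=None, seed: int = 0) -> dict:
    """Paired cross-validated goodness of fit: RoG vs MG on the same splits."""
    from .fit import pairwise_rog_fitter
    rog = goodness_of_fit(data, pairwise_rog_fitter(seed=seed), cv=cv, seed=seed)
    mg = goodness_of_fit(data, mg_fitter(seed=seed), cv=cv, seed=seed)
    return {"gof_rog": rog.score, "gof_mg": mg.score,
            "difference": rog.score - mg.score,
            "rog_folds": rog.fold_scores, "mg_folds": mg.fold_scores}
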