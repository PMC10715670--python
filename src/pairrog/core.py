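"""Pairwise Ratio-of-Gaussians model: parameter containers and closed-form moments.

The pairwise RoG describes the joint trial-to-trial activity of two neurons as

    R_i = N_i / D_i + eta_i,   i = 1, 2

where the numerators N = (N1, N2) (driving inputs), denominators D = (D1, D2)
(normalization signals) and residuals eta = (eta1, eta2) are each bivariate
Gaussian, with N and D independent of each other.  The correlation parameters
rho_N, rho_D, rho_eta couple the two neurons.  Because the exact distribution of
a ratio of Gaussians has no finite moments, the model works with a first-order
(delta-method) Gaussian approximation, valid when the denominators have
negligible probability mass at or below zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ValidityWarning",
    "PairParams",
    "MomentSet",
    "GeneralJointParams",
    "approx_moments",
    "approx_moments_general",
    "corr_decomposition",
    "stimulus_dependent_parameters",
    "stimulus_independent_parameters",
    "VALIDITY_SD_RATIO",
]

#: Minimum mu_D / sigma_D ratio below which the Gaussian approximation of the
#: ratio is considered unreliable (3 SDs bounds P(D <= 0) < 0.0014).
VALIDITY_SD_RATIO = 3.0

#: Stimulus-dependent parameters of the unreduced pairwise model: per-neuron
#: numerator/denominator means and SDs plus the two coupling correlations.
_STIM_DEPENDENT = (
    "mu_N1", "mu_N2", "mu_D1", "mu_D2",
    "sigma_N1", "sigma_N2", "sigma_D1", "sigma_D2",
    "rho_N", "rho_D",
)

#: Stimulus-independent parameters of the additive residual component.
_STIM_INDEPENDENT = ("mu_eta1", "mu_eta2", "sigma_eta1", "sigma_eta2", "rho_eta")


def stimulus_dependent_parameters() -> tuple[str, ...]:
    """Names of the unreduced model's stimulus-dependent parameters."""
    return _STIM_DEPENDENT


def stimulus_independent_parameters() -> tuple[str, ...]:
    """Names of the unreduced model's stimulus-independent (residual) parameters."""
    return _STIM_INDEPENDENT


class ValidityWarning(UserWarning):
    """Emitted when parameters leave the regime where the approximation is trusted."""


def _as_pair(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 2)
    if arr.shape != (2,):
        raise ValueError(f"{name} must be a scalar or length-2 vector, got shape {arr.shape}")
    return arr


def _check_rho(rho: float, name: str) -> float:
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"{name} must lie in [-1, 1], got {rho}")
    return rho


def _cov2(sigma: np.ndarray, rho: float) -> np.ndarray:
    off = rho * sigma[0] * sigma[1]
    return np.array([[sigma[0] ** 2, off], [off, sigma[1] ** 2]])


@dataclass
class PairParams:
    """Full stochastic specification of one neuron pair at one stimulus.

    Vectors are per-neuron (length 2).  ``mu_D`` must be strictly positive;
    this is the precondition of the Gaussian approximation to the ratio.
    """

    mu_N: np.ndarray
    mu_D: np.ndarray
    sigma_N: np.ndarray
    sigma_D: np.ndarray
    rho_N: float = 0.0
    rho_D: float = 0.0
    mu_eta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    sigma_eta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rho_eta: float = 0.0

    def __post_init__(self) -> None:
        self.mu_N = _as_pair(self.mu_N, "mu_N")
        self.mu_D = _as_pair(self.mu_D, "mu_D")
        self.sigma_N = _as_pair(self.sigma_N, "sigma_N")
        self.sigma_D = _as_pair(self.sigma_D, "sigma_D")
        self.mu_eta = _as_pair(self.mu_eta, "mu_eta")
        self.sigma_eta = _as_pair(self.sigma_eta, "sigma_eta")
        if np.any(self.mu_D <= 0):
            raise ValueError(f"mu_D must be strictly positive, got {self.mu_D}")
        for name in ("sigma_N", "sigma_D", "sigma_eta"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        self.rho_N = _check_rho(self.rho_N, "rho_N")
        self.rho_D = _check_rho(self.rho_D, "rho_D")
        self.rho_eta = _check_rho(self.rho_eta, "rho_eta")

    # -- covariance matrices -------------------------------------------------
    @property
    def cov_N(self) -> np.ndarray:
        return _cov2(self.sigma_N, self.rho_N)

    @property
    def cov_D(self) -> np.ndarray:
        return _cov2(self.sigma_D, self.rho_D)

    @property
    def cov_eta(self) -> np.ndarray:
        return _cov2(self.sigma_eta, self.rho_eta)

    @property
    def is_valid_regime(self) -> np.ndarray:
        """Per-neuron flag: mu_D / sigma_D >= 3, i.e. P(D <= 0) is negligible."""
        with np.errstate(divide="ignore"):
            ratio = np.where(self.sigma_D > 0, self.mu_D / np.maximum(self.sigma_D, 1e-300), np.inf)
        return ratio >= VALIDITY_SD_RATIO

    def warn_if_invalid(self) -> None:
        ok = self.is_valid_regime
        if not np.all(ok):
            warnings.warn(
                f"mu_D/sigma_D < {VALIDITY_SD_RATIO} for neuron(s) "
                f"{list(np.nonzero(~ok)[0] + 1)}: denominator mass at D <= 0 is "
                "not negligible and the moment approximation may be inaccurate",
                ValidityWarning,
                stacklevel=3,
            )

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "PairParams":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "PairParams":
        return cls.from_dict(json.loads(s))

    def swapped(self) -> "PairParams":
        """The same pair with neuron labels 1 and 2 exchanged."""
        return PairParams(
            mu_N=self.mu_N[::-1], mu_D=self.mu_D[::-1],
            sigma_N=self.sigma_N[::-1], sigma_D=self.sigma_D[::-1],
            rho_N=self.rho_N, rho_D=self.rho_D,
            mu_eta=self.mu_eta[::-1], sigma_eta=self.sigma_eta[::-1],
            rho_eta=self.rho_eta,
        )


@dataclass
class MomentSet:
    """First-order moments of the pair of ratio responses."""

    mu_R: np.ndarray
    var_R: np.ndarray
    cov_R: float
    corr_R: float
    corr_defined: bool = True

    def __post_init__(self) -> None:
        self.mu_R = _as_pair(self.mu_R, "mu_R")
        self.var_R = _as_pair(self.var_R, "var_R")
        self.cov_R = float(self.cov_R)
        self.corr_R = float(self.corr_R)

    @property
    def cov_matrix(self) -> np.ndarray:
        return np.array([[self.var_R[0], self.cov_R], [self.cov_R, self.var_R[1]]])

    def to_dict(self) -> dict:
        return {
            "mu_R": self.mu_R.tolist(),
            "var_R": self.var_R.tolist(),
            "cov_R": self.cov_R,
            "corr_R": self.corr_R,
            "corr_defined": self.corr_defined,
        }


@dataclass
class GeneralJointParams:
    """Joint 4-D Gaussian for (N1, N2, D1, D2) allowing numerator-denominator
    cross-correlations, plus the additive residual component.

    ``cov4`` is symmetric positive semidefinite, row-major, in the variable
    order (N1, N2, D1, D2); ``mean4[2:]`` (the denominator means) must be
    strictly positive.
    """

    mean4: np.ndarray
    cov4: np.ndarray
    mu_eta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    sigma_eta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rho_eta: float = 0.0

    def __post_init__(self) -> None:
        self.mean4 = np.asarray(self.mean4, dtype=float).reshape(4)
        self.cov4 = np.asarray(self.cov4, dtype=float).reshape(4, 4)
        self.mu_eta = _as_pair(self.mu_eta, "mu_eta")
        self.sigma_eta = _as_pair(self.sigma_eta, "sigma_eta")
        self.rho_eta = _check_rho(self.rho_eta, "rho_eta")
        if not np.allclose(self.cov4, self.cov4.T, atol=1e-10):
            raise ValueError("cov4 must be symmetric")
        eigs = np.linalg.eigvalsh(0.5 * (self.cov4 + self.cov4.T))
        if eigs.min() < -1e-8 * max(1.0, eigs.max()):
            raise ValueError("cov4 must be positive semidefinite")
        if np.any(self.mean4[2:] <= 0):
            raise ValueError("denominator means (mean4[2:]) must be strictly positive")

    @property
    def cov_eta(self) -> np.ndarray:
        return _cov2(self.sigma_eta, self.rho_eta)

    @classmethod
    def from_pair_params(cls, p: PairParams) -> "GeneralJointParams":
        cov4 = np.zeros((4, 4))
        cov4[:2, :2] = p.cov_N
        cov4[2:, 2:] = p.cov_D
        return cls(
            mean4=np.concatenate([p.mu_N, p.mu_D]),
            cov4=cov4,
            mu_eta=p.mu_eta,
            sigma_eta=p.sigma_eta,
            rho_eta=p.rho_eta,
        )

    def to_dict(self) -> dict:
        return {
            "mean4": self.mean4.tolist(),
            "cov4": self.cov4.tolist(),
            "mu_eta": self.mu_eta.tolist(),
            "sigma_eta": self.sigma_eta.tolist(),
            "rho_eta": self.rho_eta,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneralJointParams":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "GeneralJointParams":
        return cls.from_dict(json.loads(s))


def _finish_moments(mu_R: np.ndarray, var_R: np.ndarray, cov_R: float) -> MomentSet:
    var_R = np.maximum(var_R, 0.0)
    if var_R[0] > 0 and var_R[1] > 0:
        corr = float(np.clip(cov_R / np.sqrt(var_R[0] * var_R[1]), -1.0, 1.0))
        defined = True
    else:
        corr, defined = 0.0, False
    return MomentSet(mu_R=mu_R, var_R=var_R, cov_R=float(cov_R), corr_R=corr, corr_defined=defined)


def approx_moments(params: PairParams) -> MomentSet:
    """First-order delta-method moments of the pairwise ratio responses.

    Mean:      mu_R_i   = mu_N_i / mu_D_i + mu_eta_i
    Variance:  var_R_i  = (mu_N_i/mu_D_i)^2 (delta_N_i^2 + delta_D_i^2) + sigma_eta_i^2
    Covariance: (mu_N1 mu_N2)/(mu_D1 mu_D2) (rho_N d_N1 d_N2 + rho_D d_D1 d_D2)
                + rho_eta sigma_eta1 sigma_eta2

    where delta_X = sigma_X / mu_X.  Implemented in a form that avoids dividing
    by mu_N so that zero numerator means are handled.  Emits a
    :class:`ValidityWarning` when mu_D/sigma_D < 3 for either neuron.
    """
    params.warn_if_invalid()
    mu_N, mu_D = params.mu_N, params.mu_D
    s_N, s_D, s_e = params.sigma_N, params.sigma_D, params.sigma_eta

    mu_R = mu_N / mu_D + params.mu_eta
    var_R = s_N**2 / mu_D**2 + mu_N**2 * s_D**2 / mu_D**4 + s_e**2
    cov_R = (
        params.rho_N * s_N[0] * s_N[1] / (mu_D[0] * mu_D[1])
        + params.rho_D * mu_N[0] * mu_N[1] * s_D[0] * s_D[1] / (mu_D[0] ** 2 * mu_D[1] ** 2)
        + params.rho_eta * s_e[0] * s_e[1]
    )
    return _finish_moments(mu_R, var_R, cov_R)


def approx_moments_general(params: GeneralJointParams) -> MomentSet:
    """Delta-method moments for the general model with correlated numerators
    and denominators.

    The gradient of the elementwise division f(N, D) = (N1/D1, N2/D2) evaluated
    at the means sandwiches the full 4x4 covariance; the residual covariance is
    added.  Reduces exactly to :func:`approx_moments` when ``cov4`` is
    block-diagonal in (N, D).
    """
    mu = params.mean4
    mu_N, mu_D = mu[:2], mu[2:]
    sigma_D = np.sqrt(np.diag(params.cov4)[2:])
    with np.errstate(divide="ignore"):
        ratio = np.where(sigma_D > 0, mu_D / np.maximum(sigma_D, 1e-300), np.inf)
    if np.any(ratio < VALIDITY_SD_RATIO):
        warnings.warn(
            f"mu_D/sigma_D < {VALIDITY_SD_RATIO}: moment approximation may be inaccurate",
            ValidityWarning,
            stacklevel=2,
        )
    # Jacobian of (N1/D1, N2/D2) w.r.t. (N1, N2, D1, D2) at the means.
    jac = np.array(
        [
            [1.0 / mu_D[0], 0.0, -mu_N[0] / mu_D[0] ** 2, 0.0],
            [0.0, 1.0 / mu_D[1], 0.0, -mu_N[1] / mu_D[1] ** 2],
        ]
    )
    cov_R2 = jac @ params.cov4 @ jac.T + params.cov_eta
    mu_R = mu_N / mu_D + params.mu_eta
    return _finish_moments(mu_R, np.diag(cov_R2).copy(), cov_R2[0, 1])


def corr_decomposition(params: PairParams) -> tuple[float, float, float]:
    """Additive decomposition of the response correlation into numerator,
    denominator and residual contributions.

    Each term is the corresponding covariance contribution divided by the
    product of response SDs; the three terms sum to ``approx_moments(params).corr_R``.
    With no residual noise the first two terms are the familiar two-term
    rearrangement in which the numerator term is

        rho_N / sqrt((delta_D1^2/delta_N1^2 + 1)(delta_D2^2/delta_N2^2 + 1))

    and symmetrically for the denominator term.  Raises if both neurons'
    variability is exactly zero (correlation undefined).
    """
    m = approx_moments(params)
    if not m.corr_defined:
        raise ValueError("correlation undefined: at least one neuron has zero variability")
    denom = float(np.sqrt(m.var_R[0] * m.var_R[1]))
    mu_N, mu_D = params.mu_N, params.mu_D
    s_N, s_D, s_e = params.sigma_N, params.sigma_D, params.sigma_eta
    term_N = params.rho_N * s_N[0] * s_N[1] / (mu_D[0] * mu_D[1]) / denom
    term_D = (
        params.rho_D * mu_N[0] * mu_N[1] * s_D[0] * s_D[1]
        / (mu_D[0] ** 2 * mu_D[1] ** 2) / denom
    )
    term_eta = params.rho_eta * s_e[0] * s_e[1] / denom
    return float(term_N), float(term_D), float(term_eta)
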