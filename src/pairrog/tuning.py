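"""Contrast-gain-control parametrization of the pairwise RoG.

The unreduced pairwise model is over-parametrized (10 stimulus-dependent
parameters against 5 measurable per-condition statistics).  For contrast
tuning, the means of numerator and denominator follow the hyperbolic-ratio
(Naka-Rushton) factorization

    mu_N = R_max * c^2,   mu_D = epsilon^2 + c^2

so that the mean response mu_N/mu_D + R0 is the classic contrast-response
function, and the variances follow power laws of the corresponding means,
sigma^2 = alpha * mu^beta.  The coupling correlations (rho_N, rho_D, rho_eta)
are stimulus-independent.  Contrast is in percent, on [0, 100].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .core import PairParams, _check_rho

__all__ = [
    "MarginalTuning",
    "ContrastTuning",
    "contrast_drive",
    "variance_power_law",
    "build_pair_params",
]


@dataclass
class MarginalTuning:
    """Stimulus-independent parameters of one neuron's contrast response.

    Units: ``r_max`` and ``r0`` in response units; ``epsilon`` in contrast
    percent; ``alpha_n``/``alpha_d`` variance coefficients and
    ``beta_n``/``beta_d`` exponents of the power-law variance; ``sigma_eta``
    the residual SD in response units.
    """

    r_max: float
    epsilon: float
    alpha_n: float
    beta_n: float
    alpha_d: float
    beta_d: float
    r0: float = 0.0
    sigma_eta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_max", "epsilon", "alpha_n", "beta_n", "alpha_d", "beta_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sigma_eta < 0:
            raise ValueError("sigma_eta must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalTuning":
        return cls(**d)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.r_max, self.epsilon, self.alpha_n, self.beta_n,
             self.alpha_d, self.beta_d, self.r0, self.sigma_eta]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "MarginalTuning":
        return cls(*[float(v) for v in x])


@dataclass
class ContrastTuning:
    """Stimulus-independent specification of a neuron pair under contrast tuning."""

    neuron1: MarginalTuning
    neuron2: MarginalTuning
    rho_n: float = 0.0
    rho_d: float = 0.0
    rho_eta: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.neuron1, dict):
            self.neuron1 = MarginalTuning.from_dict(self.neuron1)
        if isinstance(self.neuron2, dict):
            self.neuron2 = MarginalTuning.from_dict(self.neuron2)
        self.rho_n = _check_rho(self.rho_n, "rho_n")
        self.rho_d = _check_rho(self.rho_d, "rho_d")
        self.rho_eta = _check_rho(self.rho_eta, "rho_eta")

    @property
    def neurons(self) -> tuple[MarginalTuning, MarginalTuning]:
        return (self.neuron1, self.neuron2)

    def to_dict(self) -> dict:
        return {
            "neuron1": self.neuron1.to_dict(),
            "neuron2": self.neuron2.to_dict(),
            "rho_n": self.rho_n,
            "rho_d": self.rho_d,
            "rho_eta": self.rho_eta,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ContrastTuning":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ContrastTuning":
        return cls.from_dict(json.loads(s))


def contrast_drive(c: float, tuning: ContrastTuning | MarginalTuning, neuron: int = 0):
    """Mean numerator and denominator at contrast ``c`` (percent).

    Returns ``(mu_N, mu_D) = (R_max c^2, epsilon^2 + c^2)``; the implied mean
    response mu_N/mu_D + R0 is the hyperbolic-ratio contrast-response function.
    ``neuron`` selects the pair member (0 or 1) when given a ContrastTuning.
    """
    if c < 0:
        raise ValueError(f"contrast must be non-negative, got {c}")
    m = tuning.neurons[neuron] if isinstance(tuning, ContrastTuning) else tuning
    c2 = float(c) ** 2
    return m.r_max * c2, m.epsilon**2 + c2


def variance_power_law(mu: float, alpha: float, beta: float) -> float:
    """Power-law variance sigma^2 = alpha * mu^beta.

    The implied Fano factor alpha * mu^(beta-1) is constant in mu exactly when
    beta = 1, and varies with stimulus drive otherwise.
    """
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    if mu == 0:
        return 0.0
    return alpha * mu**beta


def build_pair_params(tuning: ContrastTuning, c: float) -> PairParams:
    """Instantiate the stimulus-level pair parameters at contrast ``c``.

    Means come from :func:`contrast_drive`, SDs from the power-law variances of
    the corresponding means, the residual mean is the spontaneous rate R0, and
    the coupling correlations are copied unchanged (stimulus independence).
    """
    mu_N = np.empty(2)
    mu_D = np.empty(2)
    sigma_N = np.empty(2)
    sigma_D = np.empty(2)
    mu_eta = np.empty(2)
    sigma_eta = np.empty(2)
    for i, m in enumerate(tuning.neurons):
        mu_N[i], mu_D[i] = contrast_drive(c, m)
        sigma_N[i] = np.sqrt(variance_power_law(mu_N[i], m.alpha_n, m.beta_n))
        sigma_D[i] = np.sqrt(variance_power_law(mu_D[i], m.alpha_d, m.beta_d))
        mu_eta[i] = m.r0
        sigma_eta[i] = m.sigma_eta
    return PairParams(
        mu_N=mu_N, mu_D=mu_D, sigma_N=sigma_N, sigma_D=sigma_D,
        rho_N=tuning.rho_n, rho_D=tuning.rho_d,
        mu_eta=mu_eta, sigma_eta=sigma_eta, rho_eta=tuning.rho_eta,
    )
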