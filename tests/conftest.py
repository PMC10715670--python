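import numpy as np
import pytest

from pairrog import ContrastTuning, MarginalTuning, PairParams


@pytest.fixture
def simple_pair() -> PairParams:
    """A well-conditioned pair comfortably inside the validity regime."""
    return PairParams(
        mu_N=[50.0, 30.0], mu_D=[1.0, 1.2],
        sigma_N=[3.0, 2.0], sigma_D=[0.05, 0.06],
        rho_N=0.3, rho_D=0.4,
        mu_eta=[0.5, 0.2], sigma_eta=[0.4, 0.3], rho_eta=0.1,
    )


@pytest.fixture
def simple_tuning() -> ContrastTuning:
    n1 = MarginalTuning(r_max=30.0, epsilon=20.0, alpha_n=0.5, beta_n=1.3,
                        alpha_d=0.3, beta_d=1.2, r0=0.5, sigma_eta=0.2)
    n2 = MarginalTuning(r_max=45.0, epsilon=35.0, alpha_n=0.4, beta_n=1.5,
                        alpha_d=0.5, beta_d=1.1, r0=0.1, sigma_eta=0.3)
    return ContrastTuning(neuron1=n1, neuron2=n2, rho_n=0.3, rho_d=0.4, rho_eta=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
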