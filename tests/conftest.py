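import numpy as np
import pytest

from coexdyn import Parameters, reference_parameters


@pytest.fixture
def ref_params() -> Parameters:
    """Reference rates with the study's stated transmission rates."""
    return reference_parameters(alpha=1.37, beta=1.51)


@pytest.fixture
def toy_racism() -> Parameters:
    """Minimal racism-only fixture with R_r = 2 and round closed forms."""
    return Parameters(
        Lambda=1.0, mu=0.1, alpha=0.04, beta=0.0, omega1=1.0, omega2=1.0,
        eta=0.0, xi=0.0, sigma1=0.0, sigma2=0.0,
        gamma1=0.0, gamma2=0.1, gamma3=0.0,
        theta1=0.0, theta2=0.1, theta3=0.0,
    )


@pytest.fixture
def toy_corruption() -> Parameters:
    """Minimal corruption-only fixture with R_c = 2 and round closed forms."""
    return Parameters(
        Lambda=1.0, mu=0.1, alpha=0.0, beta=0.4, omega1=1.0, omega2=1.0,
        eta=0.0, xi=0.0, sigma1=0.0, sigma2=0.0,
        gamma1=0.1, gamma2=0.0, gamma3=0.0,
        theta1=0.1, theta2=0.0, theta3=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
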