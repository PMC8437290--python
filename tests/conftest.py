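import numpy as np
import pytest

from stochlife import GBMAllometricParams, TwoResourceParams, fig2_params, fig4_params


@pytest.fixture(scope="session")
def fig2():
    """Single-resource study parameters with the reference sigma1 = 0.5."""
    return fig2_params()


@pytest.fixture(scope="session")
def fig4():
    """Two-resource utilization study parameters."""
    return fig4_params()


def random_gbm_params(rng: np.random.Generator) -> GBMAllometricParams:
    """A random valid single-resource parameter bundle.

    Ranges span an order of magnitude around the bundled study values while
    keeping the demographic time scale 1/(f0 x^rho) short enough that all
    discounted age integrals stay within double-precision exponent range.
    """
    return GBMAllometricParams(
        b1=rng.uniform(0.05, 0.8),
        sigma1=rng.uniform(0.1, 1.0),
        x=rng.uniform(0.05, 0.5),
        mu0=rng.uniform(0.01, 0.5),
        f0=rng.uniform(0.5, 2.0),
        rho=rng.uniform(0.15, 0.85),
    )


def random_two_resource_params(rng: np.random.Generator) -> TwoResourceParams:
    """A random valid two-resource bundle (b1 >= b2, sigma1 > sigma2 >= 0)."""
    b1 = rng.uniform(0.05, 1.0)
    sigma1 = rng.uniform(0.2, 1.2)
    return TwoResourceParams(
        b1=b1,
        b2=b1 - rng.uniform(0.0, 0.6),
        sigma1=sigma1,
        sigma2=rng.uniform(0.0, 0.8) * sigma1 * 0.8,
        x=rng.uniform(0.005, 0.5),
        mu0=rng.uniform(0.01, 0.5),
        f0=rng.uniform(0.3, 2.0),
        rho=rng.uniform(0.1, 0.9),
    )
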