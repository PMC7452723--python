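import numpy as np
import pytest

from equibind import BindingParameters

NM = 1e-9
PM = 1e-12


@pytest.fixture(scope="session")
def cold_params() -> BindingParameters:
    """Slow, tight RNA-binding kinetics (0 °C-like): K_D ~ 1 pM."""
    return BindingParameters.from_rates(kon=2.85e7, koff=2.92e-5)


@pytest.fixture(scope="session")
def warm_params() -> BindingParameters:
    """Fast, weaker RNA-binding kinetics (25 °C-like): K_D ~ 130 pM."""
    return BindingParameters.from_rates(kon=1.04e8, koff=0.014)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
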