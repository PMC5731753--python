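import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from serialbump import NetworkParams, make_small_network

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def net64() -> NetworkParams:
    """Reduced 64-neuron network with the default (fixed-synapse) constants."""
    return make_small_network(64)


@pytest.fixture(scope="session")
def net64_quiet(net64) -> NetworkParams:
    """Noiseless variant of the reduced network."""
    return net64.with_(sigma_n=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
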