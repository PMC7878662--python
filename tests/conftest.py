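import numpy as np
import pytest

from prlstat5.network import (
    ModelStructure,
    build_network,
    default_initial_values,
    default_parameters,
)
from prlstat5.simulate import compile_network

CORE = ModelStructure()
FULL = ModelStructure(True, True, True)


@pytest.fixture(scope="session")
def core_network():
    return build_network(CORE)


@pytest.fixture(scope="session")
def full_network():
    return build_network(FULL)


@pytest.fixture(scope="session")
def full_model(full_network):
    return compile_network(full_network)


@pytest.fixture(scope="session")
def core_model(core_network):
    return compile_network(core_network)


@pytest.fixture(scope="session")
def full_params():
    return default_parameters(FULL)


@pytest.fixture(scope="session")
def full_init():
    return default_initial_values(FULL)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def stat5_pool(full_init):
    return sum(full_init[k] for k in ("STAT5A", "STAT5B", "STAT5A_nuc", "STAT5B_nuc"))
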