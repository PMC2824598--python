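import numpy as np
import pytest

from p53mdmx import build_network, load_parameter_set


@pytest.fixture(scope="session")
def simple_net():
    return build_network("simple")


@pytest.fixture(scope="session")
def full_net():
    return build_network("full")


@pytest.fixture(scope="session")
def col4():
    return load_parameter_set("col4")


@pytest.fixture(scope="session")
def col5():
    return load_parameter_set("col5")


@pytest.fixture(scope="session")
def col6():
    return load_parameter_set("col6")


@pytest.fixture(scope="session")
def col7():
    return load_parameter_set("col7")


@pytest.fixture(scope="session")
def col8():
    return load_parameter_set("col8")


@pytest.fixture(scope="session")
def col9():
    return load_parameter_set("col9")


@pytest.fixture(scope="session")
def fig7_params(col5):
    """Oscillatory simple-model set at the bifurcation-diagram damage level."""
    return col5.with_rates(k3=0.0086851)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
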