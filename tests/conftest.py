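import numpy as np
import pytest

from astrofilter import default_parameter_path, find_rest_state, load_parameters


@pytest.fixture(scope="session")
def params():
    """(gchi, gjc, tm) from the packaged parameter file."""
    return load_parameters(default_parameter_path())


@pytest.fixture(scope="session")
def gchi(params):
    return params[0]


@pytest.fixture(scope="session")
def gjc(params):
    return params[1]


@pytest.fixture(scope="session")
def tm(params):
    return params[2]


@pytest.fixture(scope="session")
def rest(gchi):
    return find_rest_state(gchi)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)
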