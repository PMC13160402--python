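import logging

import numpy as np
import pytest

from tubefold.model import parameters_at_temperature
from tubefold.toyparams import toy_parameter_set

logging.getLogger("tubefold").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def params():
    return toy_parameter_set(("r",), seed=0)


@pytest.fixture(scope="session")
def params_mixed():
    return toy_parameter_set(("r", "d"), seed=0)


@pytest.fixture(scope="session")
def view(params):
    return parameters_at_temperature(params, 310.15)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def corpus():
    """Random small complexes with one random ensemble member each."""
    from tubefold.fixtures import generate_fixtures

    return generate_fixtures(seed=7).corpus
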