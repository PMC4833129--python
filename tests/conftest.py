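import numpy as np
import pytest

from noddisim.schemes import build_protocol


@pytest.fixture(scope="session")
def p12345():
    return build_protocol("p12345", seed=1)


@pytest.fixture(scope="session")
def p14():
    return build_protocol("NODDI-p14", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fiber():
    mu = np.array([0.3, -0.5, 0.81])
    return mu / np.linalg.norm(mu)
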