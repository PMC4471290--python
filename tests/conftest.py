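import numpy as np
import pytest

from surfconn.mesh import make_icosphere


@pytest.fixture(scope="session")
def ico0():
    return make_icosphere(0, 1.0)


@pytest.fixture(scope="session")
def ico1():
    return make_icosphere(1, 10.0)


@pytest.fixture(scope="session")
def ico2():
    return make_icosphere(2, 42.0)


@pytest.fixture(scope="session")
def ico3():
    """Default analysis mesh: 642 vertices, ~6.3 mm edges at radius 42."""
    return make_icosphere(3, 42.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
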