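import numpy as np
import pytest

from phasefmri import fixtures as fx
from phasefmri import quadrature as qd


@pytest.fixture(scope="session")
def phantom32():
    """Structured 32^3 brain phantom plus its truth masks."""
    return fx.make_phantom_volume((32, 32, 32), "brain", seed=1)


@pytest.fixture(scope="session")
def linear_bank():
    return qd.build_filter_bank("linear")


@pytest.fixture(scope="session")
def morphon_bank():
    return qd.build_filter_bank("morphon")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
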