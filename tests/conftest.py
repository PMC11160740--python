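import numpy as np
import pytest

from cryofield import forward_model as fm
from cryofield import simulate as sim


@pytest.fixture(scope="session")
def body_spec():
    return sim.default_body()


@pytest.fixture(scope="session")
def phantom32(body_spec):
    """Standard test body rasterized at D=32 with its Hartley transform."""
    V = sim.make_phantom(body_spec, 32)
    return V, fm.dht(V)


@pytest.fixture(scope="session")
def gridded32(phantom32):
    return fm.GriddedHartleyVolume(phantom32[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
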