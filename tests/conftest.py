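import numpy as np
import pytest

from pocusalign import AlignmentConfig, load_bundled_readings
from pocusalign.phantom import PhantomConfig, generate_pair


@pytest.fixture(scope="session")
def phantom_pair():
    """Default noiseless phantom pair, seed 1."""
    return generate_pair(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def angulated_pair():
    """Phantom pair with a 12-degree dorsal angulation."""
    return generate_pair(PhantomConfig(seed=2, angulation_deg=12.0))


@pytest.fixture(scope="session")
def readings():
    """The bundled 11-sample, 3-reader study table."""
    return load_bundled_readings()


def phantom_align_config(pair) -> AlignmentConfig:
    """Alignment config matched to the phantom anatomy (d = w = bone width)."""
    return AlignmentConfig(d=pair.config.bone_width, w=pair.config.bone_width)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
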