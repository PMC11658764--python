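import numpy as np
import pytest
from hypothesis import settings

from nanocal.core_io import BinaryMask
from nanocal.synth import make_cell_mask

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

PIXEL_SIZE_UM = 0.284


@pytest.fixture(scope="session")
def pixel_size():
    return PIXEL_SIZE_UM


@pytest.fixture(scope="session")
def disk_mask():
    """A plain 5 um disk cell mask on a 96 px frame."""
    return make_cell_mask((96, 96), 5.0, PIXEL_SIZE_UM, irregularity=0.0, seed=0)


@pytest.fixture(scope="session")
def irregular_mask():
    """An amoeboid cell mask."""
    return make_cell_mask((96, 96), 5.0, PIXEL_SIZE_UM, irregularity=0.3, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(shape, rng, p=0.3):
    return BinaryMask(rng.random(shape) < p, PIXEL_SIZE_UM)
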