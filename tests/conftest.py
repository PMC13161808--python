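import numpy as np
import pytest

from fcnm.grid import BinaryMask, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid15():
    """Small 3-mm isotropic grid centered on the origin."""
    return VolumeGrid.isotropic(15, 3.0)


@pytest.fixture
def full_mask(grid15):
    return BinaryMask.full(grid15)
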