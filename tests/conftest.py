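import numpy as np
import pytest

from mrept import PhysicsConstants, ROIMask, ScalarField2D


@pytest.fixture
def consts():
    return PhysicsConstants()


@pytest.fixture
def unit_grid():
    """8x8 random field on unit spacing with a full mask."""
    rng = np.random.default_rng(7)
    f = ScalarField2D(rng.normal(size=(8, 8)), dx=1.0, dy=1.0, units="rad")
    return f, ROIMask.full((8, 8))


def random_mask(shape, rng, p_inside=0.75):
    """Random mask guaranteed to have at least one interior voxel."""
    while True:
        m = rng.random(shape) < p_inside
        mask = ROIMask(m)
        if mask.interior().any():
            return mask
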