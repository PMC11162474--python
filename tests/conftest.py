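import numpy as np
import pytest

from uqseg import BinaryMask, SampleStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0), nonempty=True):
    """Random binary mask; re-draws until nonempty when requested."""
    while True:
        grid = rng.random(shape) < p
        if grid.any() or not nonempty:
            return BinaryMask(grid=grid, spacing=spacing)


def random_stack(rng, shape=(6, 6, 6), n_members=3, n_draws=2, spacing=(1.0, 1.0, 1.0)):
    probs = rng.random((n_members, n_draws) + shape)
    return SampleStack(probs=probs, spacing=spacing)


@pytest.fixture
def mask_pair(rng):
    return random_mask(rng), random_mask(rng)
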