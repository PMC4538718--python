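import numpy as np
import pytest

from petasbench.grids import GridSpec
from petasbench.phantom import BinaryMask, PETImage
from petasbench.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Programmatically generated test volumes (sharp sphere, noisy sphere,
    necrotic spheroid), shared across the suite."""
    return make_fixtures(seed=0)


@pytest.fixture()
def small_grid():
    return GridSpec((12, 10, 8), (2.0, 2.0, 3.0), (-1.0, 0.0, 2.0))


def random_mask_pair(rng, grid):
    """Random non-trivial mask pair on a shared grid."""
    a = rng.random(grid.shape) < rng.uniform(0.1, 0.6)
    b = rng.random(grid.shape) < rng.uniform(0.1, 0.6)
    return BinaryMask(grid, a), BinaryMask(grid, b)
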