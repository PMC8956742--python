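import numpy as np
import pytest

from ecovuln.grids import Grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid(rng):
    """7x6 float grid with a few masked cells."""
    vals = rng.normal(5.0, 2.0, (7, 6))
    mask = np.ones((7, 6), dtype=bool)
    mask[0, 0] = mask[3, 2] = mask[6, 5] = False
    return Grid(values=vals, mask=mask, cell_size=30.0, origin=(1000.0, 5000.0))


@pytest.fixture
def category_grid(rng):
    """10x10 categorical grid with codes 1..4."""
    vals = rng.integers(1, 5, (10, 10)).astype(float)
    return Grid(values=vals, cell_size=30.0)
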