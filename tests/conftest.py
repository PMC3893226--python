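import numpy as np
import pytest

from reefscape import synthetic
from reefscape.grids import BathymetryGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_grid(rng):
    """A 40x40 random bathymetry grid for kernel-oracle comparisons."""
    depth = 50.0 + 5.0 * rng.standard_normal((40, 40))
    return BathymetryGrid(depth=depth, cell_size=2.0, origin=(100.0, 900.0))


@pytest.fixture
def small_scenario():
    """A fast, reduced synthetic area used by integration tests."""
    return synthetic.SyntheticScenario(name="training", n_rows=96, n_cols=120,
                                       study_cols=84, line_spacing_m=30.0, seed=7)


@pytest.fixture
def flat_grid():
    return BathymetryGrid(depth=np.full((30, 40), 50.0), cell_size=2.0)
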