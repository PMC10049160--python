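import numpy as np
import pytest

from carbonscape.raster_core import LandUseGrid
from carbonscape.synthetic import SyntheticSpec, evolve_landscape, make_drivers


@pytest.fixture
def toy_grid() -> LandUseGrid:
    """5x5 map with a small urban core and mixed classes, 100 m cells."""
    codes = np.array([
        [2, 2, 2, 3, 3],
        [2, 2, 1, 1, 3],
        [2, 1, 6, 1, 4],
        [1, 1, 6, 6, 4],
        [1, 1, 1, 5, 5],
    ])
    return LandUseGrid(codes, cell_size=100.0)


@pytest.fixture(scope="session")
def synthetic_triplet():
    """Three dated 100x100 maps with drivers and true transition probabilities."""
    spec = SyntheticSpec(shape=(100, 100), seed=11)
    maps, truths = evolve_landscape(spec, steps=2)
    return spec, maps, truths, make_drivers(spec)
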