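import numpy as np
import pytest

from ganstrip.model import DiscriminatorConfig, GeneratorConfig
from ganstrip.phantom import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_gcfg():
    """Toy-scale generator: depth 3 on 16^3 grids."""
    return GeneratorConfig(depth=3, base_filters=32, dropout_layers=1)


@pytest.fixture(scope="session")
def toy_dcfg():
    return DiscriminatorConfig(levels=3, base_filters=32)


@pytest.fixture(scope="session")
def toy_dataset():
    """10 GE phantoms on a 16^3 grid, 8 train / 2 test."""
    return make_dataset(10, 0, test_fraction=0.2, seed=11,
                        grid_shape=(16, 16, 16), voxel_size=(0.3, 0.3, 0.5))
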