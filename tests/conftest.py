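import numpy as np
import pytest

from sonoac.acoustics import ProbeConfig
from sonoac.phantom import PhantomSpec, sample_phantom


@pytest.fixture(scope="session")
def coarse_spec() -> PhantomSpec:
    """Small, fast phantom grid (64 x 38.4 mm at 0.4 mm cells)."""
    return PhantomSpec(grid_shape=(160, 96), cell_size=0.4, seed=0)


@pytest.fixture(scope="session")
def probe() -> ProbeConfig:
    return ProbeConfig()


@pytest.fixture(scope="session")
def phantom(coarse_spec):
    return sample_phantom(coarse_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
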