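import numpy as np
import pytest

from tissuefail.geometry import ConstructGeometry
from tissuefail.model import ModelParams


@pytest.fixture
def geometry():
    """Default construct: 5 µL slab, 100 µm thick."""
    return ConstructGeometry()


@pytest.fixture
def small_geometry():
    """A 0.05 µL slab (~707 µm square footprint) for dense small populations."""
    return ConstructGeometry(volume_ul=0.05, thickness_um=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_params(n_cells=500, geometry=None, **kw):
    geometry = geometry or ConstructGeometry(volume_ul=0.05, thickness_um=100.0)
    defaults = dict(n_cells=n_cells, geometry=geometry, d=0.2, lambda_int=60.0,
                    theta=0.2, beta=1.0, w_global=1.0, delta=0.3, seed=0)
    defaults.update(kw)
    return ModelParams(**defaults)
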