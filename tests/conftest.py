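import numpy as np
import pytest

from benthomap.core_io import RasterGrid
from benthomap.synthetic import ClassARModel, SimConfig


@pytest.fixture
def small_grid():
    """5x5 grid of zeros, 2.5 m cells, origin (0, 12.5)."""
    return RasterGrid(values=np.zeros((5, 5)), origin_x=0.0, origin_y=12.5, cell_size=2.5)


@pytest.fixture
def flat_cfg():
    """One-class flat-seabed survey config with beams on 1-degree bin centres."""
    return SimConfig(
        extent=250.0,
        cell_size=2.5,
        n_classes=1,
        base_depth=30.0,
        line_spacing=50.0,
        ping_spacing=2.5,
        n_beams=120,
        angular_span=60.0,
        seed=1,
    )


@pytest.fixture
def flat_model():
    """Noiseless linear angular model: mu -30 dB at 40 degrees, 0.5 dB/degree."""
    return ClassARModel(label="MB", mu=-30.0, slope=0.5, shape=8.0, noise_sd=0.0)
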