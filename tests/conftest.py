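import numpy as np
import pytest

from cortexflow.geometry import EmbryoGeometry
from cortexflow.io import VelocityField


@pytest.fixture
def geom():
    """Default 18-bin embryo geometry, 54 x 33 um, midline at y = 16.5."""
    return EmbryoGeometry(ap_extent=(0.0, 54.0), y_mid=16.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_field(vx_fn=lambda x, y: np.zeros_like(x), vy_fn=lambda x, y: np.zeros_like(x),
               spacing=2.0, extent=(54.0, 33.0), frame_index=0):
    """Regular velocity-field grid with velocities given by callables."""
    xs = np.arange(spacing / 2.0, extent[0], spacing)
    ys = np.arange(spacing / 2.0, extent[1], spacing)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    return VelocityField(x=gx, y=gy, vx=vx_fn(gx, gy), vy=vy_fn(gx, gy),
                         frame_index=frame_index)
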