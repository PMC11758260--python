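import numpy as np
import pytest

from ednatrack import (
    ReleaseSpec,
    Station,
    make_bay_field,
    make_tidal_field,
    make_uniform_field,
)


@pytest.fixture(scope="session")
def uniform_field():
    """Constant 0.1 m/s eastward flow covering a 3-day run from (5, 20) km."""
    return make_uniform_field(0.1, 0.0, extent=40_000.0, duration=300_000.0, resolution=2_000.0)


@pytest.fixture(scope="session")
def bay_field():
    """Masked bay with a tidally modulated gyre; covers one 3-day window."""
    return make_bay_field(duration=340_000.0)


@pytest.fixture(scope="session")
def bay_station():
    """A station on the mid-gyre ring of the default bay field."""
    return Station("BA", 15_000.0, 10_000.0)


@pytest.fixture
def small_spec():
    return ReleaseSpec(n_particles=20, seed=11)


def tiny_field(u, v, wet=None, nt=2, nx=3, ny=3, dx=1000.0, dt=600.0):
    """Small helper field with constant velocities (arrays broadcastable)."""
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    t = np.arange(nt) * dt
    uu = np.broadcast_to(np.asarray(u, dtype=float), (nt, ny, nx)).copy()
    vv = np.broadcast_to(np.asarray(v, dtype=float), (nt, ny, nx)).copy()
    from ednatrack import FlowField

    return FlowField(x_coords=x, y_coords=y, times=t, u=uu, v=vv, wet_mask=wet)
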