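import numpy as np
import pytest

import trutta as T


def make_uniform_field(geometry=None, velocity=(0.5, 0.0, 0.0),
                       tke=0.01, resolution=0.8):
    """Structured field with a spatially constant velocity vector."""
    g = geometry or T.FlumeGeometry()
    nx = max(5, int(round(g.length / resolution)))
    ny = max(5, int(round(g.width / 0.4)))
    nz = max(5, int(round(g.water_depth / 0.12)))
    xs = np.linspace(0.0, g.length, nx)
    ys = np.linspace(0.0, g.width, ny)
    zs = np.linspace(0.0, g.water_depth, nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vel = np.tile(np.asarray(velocity, float), (len(pts), 1))
    return T.FlowField(points=pts, velocity=vel,
                       tke=np.full(len(pts), tke),
                       alpha=np.ones(len(pts)), geometry=g,
                       grid_axes=(xs, ys, zs))


@pytest.fixture(scope="session")
def geom_jet():
    return T.FlumeGeometry(slot_present=True)


@pytest.fixture(scope="session")
def geom_nojet():
    return T.FlumeGeometry(slot_present=False)


@pytest.fixture(scope="session")
def field_jet(geom_jet):
    return T.synth_flume_field(geom_jet, jet=True, resolution=0.15, seed=1)


@pytest.fixture(scope="session")
def field_nojet(geom_nojet):
    return T.synth_flume_field(geom_nojet, jet=False, resolution=0.15, seed=1)


@pytest.fixture()
def uniform_field():
    return make_uniform_field()
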