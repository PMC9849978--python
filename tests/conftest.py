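import numpy as np
import pytest
from shapely.geometry import Polygon

from spatialaccess import CityConfig, generate_city
from spatialaccess.geodata_io import RoadNetwork


@pytest.fixture(scope="session")
def small_city():
    """A small deterministic synthetic city shared across tests."""
    return generate_city(CityConfig(seed=11, grid_nx=6, grid_ny=6,
                                    block_size=200.0, n_facilities=5,
                                    pop_total=20_000, deprivation_rho=0.6))


@pytest.fixture()
def unit_grid_polys():
    """2x2 grid of unit-square polygons, row-major from the south-west."""
    return [Polygon([(x, y), (x + 1, y), (x + 1, y + 1), (x, y + 1)])
            for y in (0, 1) for x in (0, 1)]


def grid_polys(nx, ny, size=1.0):
    return [Polygon([(x * size, y * size), ((x + 1) * size, y * size),
                     ((x + 1) * size, (y + 1) * size), (x * size, (y + 1) * size)])
            for y in range(ny) for x in range(nx)]


def path_network(edge_lengths):
    """A straight path road network with given metre edge lengths."""
    net = RoadNetwork()
    x = 0.0
    net.add_node(0, 0.0, 0.0)
    for i, length in enumerate(edge_lengths, start=1):
        x += length
        net.add_node(i, x, 0.0)
        net.add_edge(i - 1, i)
    return net


def brute_force_ann_dobs(pts):
    """O(n^2) mean nearest-neighbour distance."""
    pts = np.asarray(pts, float)
    n = len(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def brute_force_moran(values, w_dense):
    """Naive double-loop Moran's I."""
    x = np.asarray(values, float)
    z = x - x.mean()
    n = len(x)
    s0 = w_dense.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * z[i] * z[j]
    return (n / s0) * num / (z @ z)
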