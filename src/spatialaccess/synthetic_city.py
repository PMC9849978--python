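"""Reproducible synthetic cities for end-to-end testing of the pipeline.

The generator produces the minimal structures the downstream analysis
needs, with controllable spatial signal:

* a connected, jittered grid street network (metre lengths),
* census blocks tiling the extent, with integer populations allocated
  by largest remainder from a log-normal density surface optionally
  modulated by population hotspots,
* block deprivation indicators derived from a latent Gaussian field with
  tunable spatial autocorrelation (a simultaneous-autoregressive model
  on the block grid, strength ``deprivation_rho``),
* facility point patterns: complete spatial randomness (CSR), a
  Thomas-style clustered process, or caller-supplied points.

One global seed drives every sub-generator through a documented
``numpy.random.SeedSequence`` splitting scheme (children in order:
roads, population, deprivation, facilities), so stages can be
regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.sparse import identity
from scipy.sparse.linalg import spsolve
from shapely.geometry import LineString, Point, Polygon

from .geodata_io import (
    STRATA,
    CensusBlock,
    Facility,
    RoadNetwork,
    write_blocks,
    write_facilities,
    write_roads,
)
from .network_access import largest_remainder

__all__ = [
    "CityConfig",
    "SyntheticCity",
    "generate_city",
    "place_facilities",
    "latent_deprivation_field",
    "grid_rook_matrix",
]

#: Default equal-ish stratum shares (male/female x children, adults, elderly).
DEFAULT_STRATA_SHARES = (0.15, 0.32, 0.03, 0.15, 0.32, 0.03)

#: Hotspot amplitude: density multiplier at a hotspot centre is (1 + this).
HOTSPOT_AMPLITUDE = 2.0

#: Thomas-process tuning: expected offspring per parent, and offspring
#: standard deviation as a fraction of the extent width.
THOMAS_OFFSPRING_PER_PARENT = 20
THOMAS_SIGMA_FRAC = 0.02


@dataclass(frozen=True)
class CityConfig:
    """Parameters of a synthetic city.

    ``deprivation_rho`` in [0, 1) controls the neighbour correlation of
    the latent deprivation field (0 = independent blocks, 0.8 = strongly
    clustered poverty); ``pop_hotspot_centres`` is a list of
    ``(x, y, decay_radius_m)`` Gaussian population hotspots.
    """

    seed: int = 0
    grid_nx: int = 10
    grid_ny: int = 10
    block_size: float = 200.0
    road_jitter: float = 20.0
    n_facilities: int = 10
    facility_pattern: str = "csr"
    pop_total: int = 100_000
    pop_sd_log: float = 0.5
    pop_hotspot_centres: tuple[tuple[float, float, float], ...] = ()
    deprivation_rho: float = 0.6
    strata_shares: tuple[float, ...] = DEFAULT_STRATA_SHARES

    def __post_init__(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid dimensions must be at least 2x2")
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        if not (0.0 <= self.deprivation_rho < 1.0):
            raise ValueError("deprivation_rho must lie in [0, 1)")
        if len(self.strata_shares) != 6:
            raise ValueError("strata_shares must have 6 entries")
        if abs(sum(self.strata_shares) - 1.0) > 1e-9:
            raise ValueError("strata_shares must sum to 1")
        if self.n_facilities < 1:
            raise ValueError("n_facilities must be at least 1")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.grid_nx * self.block_size, self.grid_ny * self.block_size)


@dataclass
class SyntheticCity:
    roads: RoadNetwork
    blocks: list[CensusBlock]
    facilities: list[Facility]
    provenance: CityConfig
    latent_deprivation: np.ndarray = field(default=None, repr=False)

    def write(self, out_dir: str | Path) -> None:
        """Write the interchange files (GeoJSON + CSV) to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_roads(self.roads, out / "roads.geojson")
        write_blocks(self.blocks, out / "blocks.geojson",
                     out / "population.csv", out / "indicators.csv")
        write_facilities(self.facilities, out / "facilities.geojson")


# ---------------------------------------------------------------------------
# latent spatially autocorrelated field

def grid_rook_matrix(nx_: int, ny_: int):
    """Row-standardized rook adjacency of an nx x ny grid (row-major cells)."""
    from scipy.sparse import lil_matrix
    n = nx_ * ny_
    W = lil_matrix((n, n))
    for iy in range(ny_):
        for ix in range(nx_):
            i = iy * nx_ + ix
            nbrs = []
            if ix > 0:
                nbrs.append(i - 1)
            if ix < nx_ - 1:
                nbrs.append(i + 1)
            if iy > 0:
                nbrs.append(i - nx_)
            if iy < ny_ - 1:
                nbrs.append(i + nx_)
            for j in nbrs:
                W[i, j] = 1.0 / len(nbrs)
    return W.tocsr()


def latent_deprivation_field(nx_: int, ny_: int, rho: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Latent Gaussian field z = (I - rho W)^-1 e on the block grid (SAR model).

    ``rho`` in [0, 1) is the spatial-autoregressive coefficient on the
    row-standardized rook matrix W; rho -> 1 gives strongly clustered
    fields, rho = 0 white noise.  Returned standardized to mean 0, sd 1.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    n = nx_ * ny_
    e = rng.standard_normal(n)
    if rho == 0.0:
        z = e
    else:
        W = grid_rook_matrix(nx_, ny_)
        z = spsolve((identity(n) - rho * W).tocsc(), e)
    z = (z - z.mean()) / z.std()
    return z


# ---------------------------------------------------------------------------
# facilities

def place_facilities(pattern: str, n: int,
                     extent: tuple[float, float, float, float],
                     seed: int | np.random.Generator = 0,
                     points=None, year: int | None = None) -> list[Facility]:
    """Place ``n`` facility points in ``extent`` under a point-process model.

    ``csr`` is uniform (binomial) placement; ``clustered`` is a
    Thomas-style parent/offspring process (parents ~ n/20, Gaussian
    offspring spread of 2% of the extent width, offspring resampled
    until inside the extent); ``custom`` passes caller points through,
    rejecting any outside the extent.
    """
    if n < 1:
        raise ValueError("n must be at least 1 (empty pattern not analysable)")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if pattern == "csr":
        xs = rng.uniform(xmin, xmax, n)
        ys = rng.uniform(ymin, ymax, n)
        pts = np.column_stack([xs, ys])
    elif pattern == "clustered":
        n_parents = max(1, round(n / THOMAS_OFFSPRING_PER_PARENT))
        sigma = THOMAS_SIGMA_FRAC * (xmax - xmin)
        parents = np.column_stack([rng.uniform(xmin, xmax, n_parents),
                                   rng.uniform(ymin, ymax, n_parents)])
        pts = np.empty((n, 2))
        assign = rng.integers(0, n_parents, n)
        for i in range(n):
            while True:
                cand = parents[assign[i]] + rng.normal(0.0, sigma, 2)
                if xmin <= cand[0] <= xmax and ymin <= cand[1] <= ymax:
                    pts[i] = cand
                    break
    elif pattern == "custom":
        if points is None:
            raise ValueError("custom pattern requires points")
        pts = np.asarray([[p.x, p.y] if isinstance(p, Point) else tuple(p)
                          for p in points], dtype=float)
        if len(pts) != n:
            raise ValueError("custom pattern: len(points) must equal n")
        outside = [i for i, (x, y) in enumerate(pts)
                   if not (xmin <= x <= xmax and ymin <= y <= ymax)]
        if outside:
            raise ValueError(f"custom points outside extent at indices {outside[:5]}")
    else:
        raise ValueError(f"unknown facility pattern {pattern!r}")

    return [Facility(f"F{i:04d}", Point(float(x), float(y)), year)
            for i, (x, y) in enumerate(pts)]


# ---------------------------------------------------------------------------
# city generation

_MAX_ROAD_RETRIES = 5


def generate_city(config: CityConfig) -> SyntheticCity:
    """Generate a complete synthetic city from a validated config.

    Deterministic for a fixed config (the global seed is split into
    per-stage child seeds).  The road graph is guaranteed connected;
    blocks tile the extent without overlap; populations are integers
    conserving ``pop_total`` exactly.
    """
    ss = np.random.SeedSequence(config.seed)
    roads_ss, pop_ss, depr_ss, fac_ss = ss.spawn(4)

    roads = _generate_roads(config, np.random.default_rng(roads_ss))
    blocks, latent = _generate_blocks(config,
                                      np.random.default_rng(pop_ss),
                                      np.random.default_rng(depr_ss))
    facilities = place_facilities(config.facility_pattern, config.n_facilities,
                                  config.extent,
                                  np.random.default_rng(fac_ss))
    return SyntheticCity(roads=roads, blocks=blocks, facilities=facilities,
                         provenance=config, latent_deprivation=latent)


def _generate_roads(config: CityConfig, rng: np.random.Generator) -> RoadNetwork:
    """Jittered grid street graph over the city extent; retries on disconnect."""
    nxn, nyn = config.grid_nx + 1, config.grid_ny + 1
    bs = config.block_size
    for attempt in range(_MAX_ROAD_RETRIES):
        net = RoadNetwork()
        for iy in range(nyn):
            for ix in range(nxn):
                x, y = ix * bs, iy * bs
                # jitter interior nodes only, keeping the boundary frame
                if 0 < ix < nxn - 1 and 0 < iy < nyn - 1 and config.road_jitter > 0:
                    # clip so nodes cannot collide across a block
                    j = min(config.road_jitter, 0.45 * bs)
                    x += rng.uniform(-j, j)
                    y += rng.uniform(-j, j)
                net.add_node(iy * nxn + ix, x, y)
        for iy in range(nyn):
            for ix in range(nxn):
                i = iy * nxn + ix
                if ix < nxn - 1:
                    net.add_edge(i, i + 1)
                if iy < nyn - 1:
                    net.add_edge(i, i + nxn)
        if net.is_connected():
            return net
    raise RuntimeError(
        f"road graph disconnected after {_MAX_ROAD_RETRIES} attempts "
        f"(jitter {config.road_jitter} m too large for block size {config.block_size} m)")


def _generate_blocks(config: CityConfig, pop_rng: np.random.Generator,
                     depr_rng: np.random.Generator
                     ) -> tuple[list[CensusBlock], np.ndarray]:
    nx_, ny_ = config.grid_nx, config.grid_ny
    bs = config.block_size
    n = nx_ * ny_

    # population density: log-normal block weights modulated by hotspots
    logw = pop_rng.normal(0.0, config.pop_sd_log, n)
    weight = np.exp(logw)
    centres_x = (np.arange(nx_) + 0.5) * bs
    centres_y = (np.arange(ny_) + 0.5) * bs
    cx, cy = np.meshgrid(centres_x, centres_y)  # shape (ny, nx), row-major
    cx, cy = cx.ravel(), cy.ravel()
    for hx, hy, hr in config.pop_hotspot_centres:
        d2 = (cx - hx) ** 2 + (cy - hy) ** 2
        weight *= 1.0 + HOTSPOT_AMPLITUDE * np.exp(-d2 / (2.0 * hr ** 2))

    exact_tot = weight / weight.sum() * config.pop_total
    block_totals = largest_remainder(list(exact_tot), config.pop_total)

    latent = latent_deprivation_field(nx_, ny_, config.deprivation_rho, depr_rng)

    blocks: list[CensusBlock] = []
    for iy in range(ny_):
        for ix in range(nx_):
            i = iy * nx_ + ix
            poly = Polygon([(ix * bs, iy * bs), ((ix + 1) * bs, iy * bs),
                            ((ix + 1) * bs, (iy + 1) * bs), (ix * bs, (iy + 1) * bs)])
            tot = block_totals[i]
            exact = [tot * s for s in config.strata_shares]
            counts = largest_remainder(exact, tot)
            pop = dict(zip(STRATA, counts))
            blocks.append(CensusBlock(
                block_id=f"B{i:04d}", polygon=poly, pop=pop,
                indicators=_indicators_from_latent(latent[i], block_totals[i],
                                                   bs, depr_rng)))
    return blocks, latent


def _indicators_from_latent(z: float, block_pop: int, block_size: float,
                            rng: np.random.Generator) -> dict[str, float]:
    """Plausible indicator scales driven by one latent deprivation value.

    Each indicator is a monotone transform of the latent z plus small
    independent noise, on a realistic scale: unemployment and illiteracy
    as bounded percentages rising with deprivation, literacy falling,
    dependency ratio and household size rising.
    """
    def logistic(a):
        return 1.0 / (1.0 + math.exp(-a))

    eps = rng.normal(0.0, 0.15, 5)
    return {
        "unemployment_rate": 100.0 * logistic(-1.5 + 0.8 * z + eps[0]),
        "illiteracy_rate": 100.0 * logistic(-1.8 + 0.9 * z + eps[1]),
        "literacy_rate": 100.0 * logistic(1.8 - 0.9 * z + eps[2]),
        "dependency_ratio": max(5.0, 50.0 + 15.0 * z + 5.0 * eps[3]),
        "household_size": max(1.5, 3.5 + 0.6 * z + 0.2 * eps[4]),
        "population_density": block_pop / (block_size ** 2 / 1e6),  # persons/km^2
    }
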