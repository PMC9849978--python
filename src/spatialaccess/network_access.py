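"""Walking-time accessibility on a street network.

The accessibility model: each facility is snapped to its nearest street
edge; a single-source shortest-path search (edge cost = length / walking
speed) delimits the territory reachable within the time budget, including
partially covered edges at the frontier; the reached edge portions are
buffered into a service-area polygon; service areas are unioned into a
coverage polygon; census-block populations are intersected with coverage
(areal split or centroid assignment) and tabulated per sex x age stratum
into an access / no-access table.

Defaults follow the standard pedestrian-access convention: walking speed
1 m/s and a 750 m service radius, i.e. a 12.5-minute walking-time cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import substring, unary_union

from .geodata_io import AGE_BANDS, SEXES, STRATA, CensusBlock, Facility, RoadNetwork

__all__ = [
    "WalkModel",
    "NetworkPosition",
    "ServiceArea",
    "AccessTable",
    "snap_facility",
    "service_area",
    "union_service_areas",
    "euclidean_coverage",
    "population_with_access",
    "tabulate_access",
    "round_half_up",
    "pct_half_up",
    "largest_remainder",
]

DEFAULT_SNAP_TOL = 200.0   # m
DEFAULT_BUFFER_WIDTH = 50.0  # m, service-area polygonization half-width


@dataclass(frozen=True)
class WalkModel:
    """Pedestrian travel model: speed (m/s) and service radius (m).

    The travel-time cutoff is ``radius / speed`` seconds — 750 m at
    1 m/s gives 750 s = 12.5 min.
    """

    speed: float = 1.0
    radius: float = 750.0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("walking speed must be positive")
        if self.radius <= 0:
            raise ValueError("service radius must be positive")

    @property
    def cutoff_s(self) -> float:
        return self.radius / self.speed

    @property
    def cutoff_min(self) -> float:
        return self.cutoff_s / 60.0


@dataclass(frozen=True)
class NetworkPosition:
    """A location on the network: an edge and the metre offset from its u end."""

    u: int
    v: int
    offset_m: float
    point: Point
    snap_dist_m: float


def _canonical_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u <= v else (v, u)


def snap_facility(net: RoadNetwork, facility: Facility,
                  max_tol: float = DEFAULT_SNAP_TOL) -> NetworkPosition:
    """Snap a facility to the foot of perpendicular on its nearest edge.

    Ties between equidistant edges are broken by the lowest canonical
    edge id ``(min(u,v), max(u,v))``.  Facilities farther than
    ``max_tol`` metres from every edge are an error, never dropped.
    """
    best = None
    p = facility.point
    for u, v, length, geom in net.edges():
        d = geom.distance(p)
        key = (d, _canonical_edge(u, v))
        if best is None or key < best[0]:
            off = geom.project(p)
            cu, cv = _canonical_edge(u, v)
            # offset measured from the canonical u end
            off_c = off if (cu, cv) == (u, v) else geom.length - off
            # rescale geometric offset to declared length
            off_m = off_c * length / geom.length
            best = (key, NetworkPosition(cu, cv, off_m, geom.interpolate(off), d))
    if best is None:
        raise ValueError("road network has no edges")
    if best[0][0] > max_tol:
        raise ValueError(
            f"facility {facility.facility_id} is {best[0][0]:.1f} m from the "
            f"nearest edge (tolerance {max_tol} m)")
    return best[1]


@dataclass
class ServiceArea:
    """Network territory reachable from one facility within the time budget.

    ``reached`` maps canonical edges to a list of covered metre-intervals
    along the edge (measured from the canonical u end); ``node_times``
    holds shortest-path times (s) of reached nodes; ``polygon`` is the
    buffered footprint of the covered edge portions.
    """

    facility_id: str
    cutoff_s: float
    node_times: dict[int, float]
    reached: dict[tuple[int, int], list[tuple[float, float]]]
    polygon: object  # shapely (Multi)Polygon
    position: NetworkPosition


def _merge_intervals(ivals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    ivals = sorted((a, b) for a, b in ivals if b > a)
    out: list[tuple[float, float]] = []
    for a, b in ivals:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def service_area(net: RoadNetwork, position: NetworkPosition,
                 model: WalkModel, facility_id: str = "",
                 buffer_width: float = DEFAULT_BUFFER_WIDTH,
                 cutoff_s: float | None = None) -> ServiceArea:
    """Walking-time service area from a snapped network position.

    Runs Dijkstra from the snapped point (entering the network at both
    ends of the snap edge), then covers every edge up to the residual
    time budget at each end, yielding partial-edge coverage at the
    frontier.  The polygon is the union of covered edge portions
    buffered by ``buffer_width``; a zero or tiny cutoff degenerates to
    the buffer disc around the snap point.
    """
    cutoff = model.cutoff_s if cutoff_s is None else max(0.0, cutoff_s)
    g = net.graph
    u, v, off = position.u, position.v, position.offset_m
    edge_len = g.edges[u, v]["length_m"]

    node_times: dict[int, float] = {}
    if cutoff > 0:
        src = ("__sa_src__",)
        g.add_node(src)
        g.add_edge(src, u, length_m=max(off, 0.0))
        g.add_edge(src, v, length_m=max(edge_len - off, 0.0))
        try:
            # travel time = length / speed
            times = nx.single_source_dijkstra_path_length(
                g, src, cutoff=cutoff, weight=lambda a, b, d: d["length_m"] / model.speed)
        finally:
            g.remove_node(src)
        node_times = {n: t for n, t in times.items() if n != src}

    reached: dict[tuple[int, int], list[tuple[float, float]]] = {}

    # direct coverage along the snap edge from the interior point
    reach_m = cutoff * model.speed
    a0, b0 = max(0.0, off - reach_m), min(edge_len, off + reach_m)
    ce = _canonical_edge(u, v)
    snap_cov = [(a0, b0)] if b0 > a0 else []

    for eu, ev, d in g.edges(data=True):
        length = d["length_m"]
        t_u = node_times.get(eu, math.inf)
        t_v = node_times.get(ev, math.inf)
        ivals = []
        if t_u <= cutoff:
            ivals.append((0.0, min(length, (cutoff - t_u) * model.speed)))
        if t_v <= cutoff:
            ivals.append((max(0.0, length - (cutoff - t_v) * model.speed), length))
        key = _canonical_edge(eu, ev)
        if key == ce:
            # orient intervals from the canonical u end
            if (eu, ev) != key:
                ivals = [(length - b, length - a) for a, b in ivals]
            ivals = ivals + snap_cov
        elif (eu, ev) != key:
            ivals = [(length - b, length - a) for a, b in ivals]
        merged = _merge_intervals(ivals)
        if merged:
            reached[key] = merged

    # polygonize: buffer covered portions of edge geometries
    parts = [position.point.buffer(buffer_width)]
    for (eu, ev), ivals in reached.items():
        d = g.edges[eu, ev]
        geom, length = d["geometry"], d["length_m"]
        # geometry runs u->v as stored; orient to canonical direction
        stored_uv = _first_stored_orientation(net, eu, ev)
        for a, b in ivals:
            ga, gb = a / length * geom.length, b / length * geom.length
            if not stored_uv:
                ga, gb = geom.length - gb, geom.length - ga
            seg = substring(geom, ga, gb)
            if seg.length > 0 or not seg.is_empty:
                parts.append(seg.buffer(buffer_width))
    poly = unary_union(parts)
    return ServiceArea(facility_id=facility_id, cutoff_s=cutoff,
                       node_times=node_times, reached=reached,
                       polygon=poly, position=position)


def _first_stored_orientation(net: RoadNetwork, u: int, v: int) -> bool:
    """True if the stored geometry of edge (u, v) starts at min(u, v)."""
    cu, _ = _canonical_edge(u, v)
    geom = net.graph.edges[u, v]["geometry"]
    x, y = net.node_xy(cu)
    gx, gy = geom.coords[0]
    return math.isclose(gx, x, abs_tol=1e-6) and math.isclose(gy, y, abs_tol=1e-6)


def union_service_areas(areas: list[ServiceArea]):
    """Geometric union of service-area polygons (order-independent, idempotent)."""
    if not areas:
        raise ValueError("need at least one service area")
    return unary_union([a.polygon for a in areas])


def euclidean_coverage(facilities: list[Facility], radius: float):
    """Straight-line comparison baseline: union of radius-discs around facilities."""
    if not facilities:
        raise ValueError("need at least one facility")
    return unary_union([f.point.buffer(radius) for f in facilities])


# ---------------------------------------------------------------------------
# population overlay

def population_with_access(blocks: list[CensusBlock], coverage,
                           method: str = "areal") -> dict[str, float]:
    """Per-block fraction of population with access to the coverage polygon.

    ``areal`` splits each block's population in proportion to the block
    area inside coverage; ``centroid`` assigns all-or-nothing by centroid
    containment.  Zero-area blocks fall back to the centroid rule with a
    warning.
    """
    if method not in ("areal", "centroid"):
        raise ValueError(f"unknown overlay method {method!r}")
    fractions: dict[str, float] = {}
    for b in blocks:
        if b.polygon.area == 0:
            warnings.warn(f"block {b.block_id} has zero area; using centroid rule")
            fractions[b.block_id] = float(coverage.contains(b.polygon.centroid))
        elif method == "centroid":
            fractions[b.block_id] = float(coverage.contains(b.polygon.centroid))
        else:
            fractions[b.block_id] = b.polygon.intersection(coverage).area / b.polygon.area
    return fractions


# ---------------------------------------------------------------------------
# tabulation

def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as used for printed percentages."""
    q = 10 ** decimals
    return math.floor(x * q + 0.5) / q


def pct_half_up(count: int, total: int, decimals: int = 2) -> float:
    """100*count/total rounded half-up, in exact integer arithmetic.

    Avoids binary-float boundary errors (e.g. a true percentage of
    exactly x.xx5 must round up).
    """
    q = 10 ** decimals
    # floor(100*count*q/total + 1/2) without floats
    return (200 * count * q + total) // (2 * total) / q


def largest_remainder(exact: list[float], total: int) -> list[int]:
    """Integer allocation of ``total`` proportional to ``exact`` (largest remainder).

    ``exact`` must sum to ``total`` (within numerical tolerance); the
    returned integers sum to exactly ``total``.
    """
    floors = [math.floor(e) for e in exact]
    rem = total - sum(floors)
    if rem < 0 or rem > len(exact):
        raise ValueError("exact values do not sum to total")
    # distribute remainder to largest fractional parts; ties by index
    order = sorted(range(len(exact)), key=lambda i: (-(exact[i] - floors[i]), i))
    out = list(floors)
    for i in order[:rem]:
        out[i] += 1
    return out


@dataclass
class AccessTable:
    """Access / no-access counts and percentages per stratum for one census wave.

    Cells are the six sex x age strata plus per-sex totals and the grand
    total.  Per cell: access + no_access = total exactly (integer counts,
    largest-remainder rounding); percentages are 100*count/total rounded
    half-up to 2 decimals, or None where the total is zero.
    """

    year: int | None
    access: dict[str, int] = field(default_factory=dict)
    no_access: dict[str, int] = field(default_factory=dict)
    total: dict[str, int] = field(default_factory=dict)

    CELLS = tuple(list(STRATA)
                  + [f"{s}_total" for s in SEXES]
                  + [f"total_{a}" for a in AGE_BANDS]
                  + ["total"])

    def access_pct(self, cell: str) -> float | None:
        if self.total[cell] == 0:
            return None
        return pct_half_up(self.access[cell], self.total[cell])

    def no_access_pct(self, cell: str) -> float | None:
        if self.total[cell] == 0:
            return None
        return pct_half_up(self.no_access[cell], self.total[cell])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cell in self.CELLS:
            rows.append({
                "year": self.year, "cell": cell,
                "access_n": self.access[cell], "no_access_n": self.no_access[cell],
                "total_n": self.total[cell],
                "access_pct": self.access_pct(cell),
                "no_access_pct": self.no_access_pct(cell),
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_counts(cls, access: dict[str, int], total: dict[str, int],
                    year: int | None = None) -> "AccessTable":
        """Build a table from integer access counts and totals per stratum.

        Marginal cells (per-sex, per-age and grand totals) are derived by
        summation when only the six strata are given.
        """
        t = cls(year=year)
        for s in STRATA:
            t.access[s] = int(access[s])
            t.total[s] = int(total[s])
            t.no_access[s] = t.total[s] - t.access[s]
            if t.no_access[s] < 0:
                raise ValueError(f"stratum {s}: access exceeds total")
        t._fill_margins()
        return t

    def _fill_margins(self) -> None:
        for sex in SEXES:
            cells = [f"{sex}_{a}" for a in AGE_BANDS]
            self.access[f"{sex}_total"] = sum(self.access[c] for c in cells)
            self.no_access[f"{sex}_total"] = sum(self.no_access[c] for c in cells)
            self.total[f"{sex}_total"] = sum(self.total[c] for c in cells)
        for a in AGE_BANDS:
            cells = [f"{sex}_{a}" for sex in SEXES]
            self.access[f"total_{a}"] = sum(self.access[c] for c in cells)
            self.no_access[f"total_{a}"] = sum(self.no_access[c] for c in cells)
            self.total[f"total_{a}"] = sum(self.total[c] for c in cells)
        self.access["total"] = sum(self.access[s] for s in STRATA)
        self.no_access["total"] = sum(self.no_access[s] for s in STRATA)
        self.total["total"] = sum(self.total[s] for s in STRATA)


def tabulate_access(fractions: dict[str, float], blocks: list[CensusBlock],
                    year: int | None = None) -> AccessTable:
    """Tabulate per-stratum access counts from per-block access fractions.

    Within each stratum the exact (fractional) access and no-access
    person counts are rounded by largest remainder so that
    access + no_access equals the stratum total exactly.
    """
    missing = [b.block_id for b in blocks if b.block_id not in fractions]
    if missing:
        raise ValueError(f"no access fraction for blocks: {missing[:5]}")
    access: dict[str, int] = {}
    total: dict[str, int] = {}
    for s in STRATA:
        tot = sum(b.pop.get(s, 0) for b in blocks)
        exact_acc = sum(fractions[b.block_id] * b.pop.get(s, 0) for b in blocks)
        acc, _ = largest_remainder([exact_acc, tot - exact_acc], tot)
        access[s] = acc
        total[s] = tot
    return AccessTable.from_counts(access, total, year=year)
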