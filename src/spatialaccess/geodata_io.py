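"""Interchange-file I/O and shared geometric domain types.

All geometry is planar, in metres, in a projected CRS. Inputs whose
coordinates look like geographic degrees (every x in [-180, 180] and every
y in [-90, 90]) are rejected with an error instructing the user to project
to a metric CRS first; this package never reprojects.

Readers validate and reject rather than silently repair; error messages
name the offending feature id or column. Writers emit RFC 7946 GeoJSON
FeatureCollections and comma-separated UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml
from shapely.geometry import LineString, Point, Polygon, mapping, shape

__all__ = [
    "STRATA",
    "AGE_BANDS",
    "SEXES",
    "RoadNetwork",
    "CensusBlock",
    "Facility",
    "GeodataError",
    "read_roads",
    "write_roads",
    "read_blocks",
    "write_blocks",
    "read_facilities",
    "write_facilities",
    "write_access_table",
    "read_config",
]

#: Population strata: 2 sexes x 3 age bands (children 0-14, adults 15-64,
#: elderly 65+), the stratification used throughout the access tabulation.
SEXES = ("male", "female")
AGE_BANDS = ("0_14", "15_64", "65p")
STRATA = tuple(f"{s}_{a}" for s in SEXES for a in AGE_BANDS)


class GeodataError(ValueError):
    """Raised for any validation failure in interchange files."""


@dataclass(frozen=True)
class Facility:
    """A health-facility point with the census wave it belongs to."""

    facility_id: str
    point: Point
    year: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.point.x) and math.isfinite(self.point.y)):
            raise GeodataError(f"facility {self.facility_id}: non-finite coordinates")


@dataclass
class CensusBlock:
    """A census block polygon with stratified population counts and raw indicators.

    ``pop`` maps each of the six strata in :data:`STRATA` to a nonnegative
    integer count; ``indicators`` maps indicator names to raw real values.
    """

    block_id: str
    polygon: Polygon
    pop: dict[str, int] = field(default_factory=dict)
    indicators: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise GeodataError(f"block {self.block_id}: invalid or empty polygon")
        for k, v in self.pop.items():
            if k not in STRATA:
                raise GeodataError(f"block {self.block_id}: unknown stratum {k!r}")
            if v < 0 or int(v) != v:
                raise GeodataError(
                    f"block {self.block_id}: stratum {k} count {v!r} is not a nonnegative integer"
                )

    @property
    def total(self) -> int:
        return int(sum(self.pop.values()))


class RoadNetwork:
    """An undirected street graph with metre edge lengths and line geometries.

    Nodes are integer ids with planar ``(x, y)`` coordinates in metres;
    each edge carries ``length_m`` (> 0, within 0.1% of the geometric
    length of its polyline) and a shapely ``LineString`` geometry.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, node_id: int, x: float, y: float) -> None:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise GeodataError(f"node {node_id}: non-finite coordinates")
        self.graph.add_node(node_id, x=float(x), y=float(y))

    def add_edge(self, u: int, v: int, geometry: LineString | None = None,
                 length_m: float | None = None) -> None:
        if geometry is None:
            geometry = LineString([self.node_xy(u), self.node_xy(v)])
        if length_m is None:
            length_m = geometry.length
        if length_m <= 0:
            raise GeodataError(f"edge ({u}, {v}): nonpositive length {length_m}")
        if geometry.length > 0 and abs(length_m - geometry.length) > 1e-3 * geometry.length:
            raise GeodataError(
                f"edge ({u}, {v}): declared length {length_m} deviates >0.1% "
                f"from geometric length {geometry.length}"
            )
        self.graph.add_edge(u, v, length_m=float(length_m), geometry=geometry)

    def node_xy(self, node_id: int) -> tuple[float, float]:
        d = self.graph.nodes[node_id]
        return d["x"], d["y"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[int, int, float, LineString]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["length_m"], d["geometry"]

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def bounds(self) -> tuple[float, float, float, float]:
        xs = [d["x"] for _, d in self.graph.nodes(data=True)]
        ys = [d["y"] for _, d in self.graph.nodes(data=True)]
        return min(xs), min(ys), max(xs), max(ys)


# ---------------------------------------------------------------------------
# helpers

def _check_planar(coords: Iterable[tuple[float, float]], context: str) -> None:
    """Reject coordinate sets that look like geographic lon/lat degrees."""
    coords = list(coords)
    if not coords:
        return
    for x, y in coords:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise GeodataError(f"{context}: non-finite coordinate ({x}, {y})")
    if all(-180.0 <= x <= 180.0 and -90.0 <= y <= 90.0 for x, y in coords):
        raise GeodataError(
            f"{context}: coordinates lie within lon/lat degree ranges; "
            "inputs must be in a projected metric CRS (metres) — "
            "reproject before loading"
        )


def _load_feature_collection(path: str | Path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection" or "features" not in doc:
        raise GeodataError(f"{path}: not a GeoJSON FeatureCollection")
    return doc["features"]


def _dump_feature_collection(features: list[dict], path: str | Path) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, separators=(",", ":"))
        fh.write("\n")


# ---------------------------------------------------------------------------
# roads

def read_roads(path: str | Path) -> RoadNetwork:
    """Read a road network from a GeoJSON of LineString features.

    Node ids are taken from ``u``/``v`` feature properties when present;
    otherwise endpoints are matched by exact coordinates.
    """
    feats = _load_feature_collection(path)
    net = RoadNetwork()
    coord_to_id: dict[tuple[float, float], int] = {}
    all_coords: list[tuple[float, float]] = []

    def node_for(xy: tuple[float, float], explicit: int | None) -> int:
        if explicit is not None:
            nid = int(explicit)
        else:
            nid = coord_to_id.setdefault(xy, len(coord_to_id))
        if nid not in net.graph:
            net.add_node(nid, *xy)
        return nid

    for i, feat in enumerate(feats):
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise GeodataError(f"{path}: feature {i} is not a LineString")
        props = feat.get("properties") or {}
        all_coords.extend((float(x), float(y)) for x, y in geom.coords)
        start = (float(geom.coords[0][0]), float(geom.coords[0][1]))
        end = (float(geom.coords[-1][0]), float(geom.coords[-1][1]))
        u = node_for(start, props.get("u"))
        v = node_for(end, props.get("v"))
        length = props.get("length_m")
        net.add_edge(u, v, geometry=geom,
                     length_m=float(length) if length is not None else None)
    _check_planar(all_coords, str(path))
    return net


def write_roads(net: RoadNetwork, path: str | Path) -> None:
    feats = []
    for u, v, length, geom in sorted(net.edges(), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
        feats.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"u": int(u), "v": int(v), "length_m": length},
        })
    _dump_feature_collection(feats, path)


# ---------------------------------------------------------------------------
# blocks

def read_blocks(geo_path: str | Path, pop_path: str | Path | None = None,
                ind_path: str | Path | None = None) -> list[CensusBlock]:
    """Read census blocks: polygon GeoJSON plus population / indicator CSVs.

    The CSVs are keyed by ``block_id`` and must match the geometry ids
    exactly (no extras, no missing). The population CSV must contain all
    six stratum columns of :data:`STRATA`.
    """
    feats = _load_feature_collection(geo_path)
    blocks: list[CensusBlock] = []
    seen: set[str] = set()
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        bid = props.get("block_id")
        if bid is None:
            raise GeodataError(f"{geo_path}: feature {i} has no block_id property")
        bid = str(bid)
        if bid in seen:
            raise GeodataError(f"{geo_path}: duplicate block_id {bid}")
        seen.add(bid)
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise GeodataError(f"{geo_path}: block {bid} is not a Polygon")
        if not geom.is_valid:
            raise GeodataError(f"{geo_path}: block {bid} polygon is invalid "
                               "(self-intersecting or degenerate)")
        _check_planar(list(geom.exterior.coords), f"{geo_path} block {bid}")
        blocks.append(CensusBlock(block_id=bid, polygon=geom))

    by_id = {b.block_id: b for b in blocks}

    if pop_path is not None:
        pop = pd.read_csv(pop_path, dtype={"block_id": str})
        if "block_id" not in pop.columns:
            raise GeodataError(f"{pop_path}: missing column block_id")
        for col in STRATA:
            if col not in pop.columns:
                raise GeodataError(f"{pop_path}: missing stratum column {col}")
        _match_ids(set(pop["block_id"]), set(by_id), str(pop_path))
        for _, row in pop.iterrows():
            b = by_id[row["block_id"]]
            b.pop = {}
            for col in STRATA:
                val = row[col]
                if pd.isna(val) or val < 0 or int(val) != val:
                    raise GeodataError(
                        f"{pop_path}: block {b.block_id} column {col}: "
                        f"{val!r} is not a nonnegative integer")
                b.pop[col] = int(val)

    if ind_path is not None:
        ind = pd.read_csv(ind_path, dtype={"block_id": str})
        if "block_id" not in ind.columns:
            raise GeodataError(f"{ind_path}: missing column block_id")
        _match_ids(set(ind["block_id"]), set(by_id), str(ind_path))
        value_cols = [c for c in ind.columns if c != "block_id"]
        for _, row in ind.iterrows():
            b = by_id[row["block_id"]]
            b.indicators = {c: float(row[c]) for c in value_cols}

    return blocks


def _match_ids(csv_ids: set[str], geo_ids: set[str], context: str) -> None:
    missing = geo_ids - csv_ids
    extra = csv_ids - geo_ids
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"ids missing from CSV: {sorted(missing)[:5]}")
        if extra:
            parts.append(f"ids absent from geometry: {sorted(extra)[:5]}")
        raise GeodataError(f"{context}: block_id mismatch — " + "; ".join(parts))


def write_blocks(blocks: list[CensusBlock], geo_path: str | Path,
                 pop_path: str | Path | None = None,
                 ind_path: str | Path | None = None) -> None:
    feats = []
    for b in blocks:
        feats.append({
            "type": "Feature",
            "geometry": mapping(b.polygon),
            "properties": {"block_id": b.block_id},
        })
    _dump_feature_collection(feats, geo_path)
    if pop_path is not None:
        rows = [{"block_id": b.block_id, **{s: b.pop.get(s, 0) for s in STRATA}}
                for b in blocks]
        pd.DataFrame(rows).to_csv(pop_path, index=False)
    if ind_path is not None:
        names = sorted({k for b in blocks for k in b.indicators})
        rows = [{"block_id": b.block_id, **{n: b.indicators.get(n, float("nan")) for n in names}}
                for b in blocks]
        pd.DataFrame(rows).to_csv(ind_path, index=False)


# ---------------------------------------------------------------------------
# facilities

def read_facilities(path: str | Path) -> list[Facility]:
    """Read facilities from GeoJSON Points or a CSV with x,y columns."""
    path = Path(path)
    out: list[Facility] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        for col in ("x", "y"):
            if col not in df.columns:
                raise GeodataError(f"{path}: missing column {col}")
        for i, row in df.iterrows():
            fid = str(row["facility_id"]) if "facility_id" in df.columns else f"F{i:04d}"
            year = int(row["year"]) if "year" in df.columns and not pd.isna(row["year"]) else None
            out.append(Facility(fid, Point(float(row["x"]), float(row["y"])), year))
    else:
        for i, feat in enumerate(_load_feature_collection(path)):
            geom = shape(feat["geometry"])
            if not isinstance(geom, Point):
                raise GeodataError(f"{path}: feature {i} is not a Point")
            props = feat.get("properties") or {}
            fid = str(props.get("facility_id", f"F{i:04d}"))
            year = props.get("year")
            out.append(Facility(fid, geom, int(year) if year is not None else None))
    _check_planar([(f.point.x, f.point.y) for f in out], str(path))
    return out


def write_facilities(facilities: list[Facility], path: str | Path) -> None:
    feats = []
    for f in facilities:
        props: dict = {"facility_id": f.facility_id}
        if f.year is not None:
            props["year"] = int(f.year)
        feats.append({
            "type": "Feature",
            "geometry": mapping(f.point),
            "properties": props,
        })
    _dump_feature_collection(feats, path)


# ---------------------------------------------------------------------------
# tables and config

def write_access_table(table: "pd.DataFrame | object", path: str | Path) -> None:
    """Write an access table (or any object exposing ``to_dataframe``) as CSV."""
    df = table if isinstance(table, pd.DataFrame) else table.to_dataframe()
    df.to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    """Read a YAML run-configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise GeodataError(f"{path}: config must be a key-value mapping")
    return dict(cfg)
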