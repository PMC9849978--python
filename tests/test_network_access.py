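"""Service-area, overlay and tabulation tests, with an exhaustive path oracle."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from spatialaccess.geodata_io import STRATA, CensusBlock, Facility, RoadNetwork
from spatialaccess.network_access import (
    AccessTable,
    WalkModel,
    euclidean_coverage,
    largest_remainder,
    population_with_access,
    pct_half_up,
    service_area,
    snap_facility,
    tabulate_access,
    union_service_areas,
)

from conftest import path_network


def exhaustive_reach_times(net, source, speed=1.0):
    """Oracle: minimum travel time to each node over ALL simple paths."""
    g = net.graph
    best = {source: 0.0}
    for target in g.nodes:
        if target == source:
            continue
        tmin = math.inf
        for path in nx.all_simple_paths(g, source, target):
            t = sum(g.edges[a, b]["length_m"] / speed
                    for a, b in zip(path, path[1:]))
            tmin = min(tmin, t)
        if tmin < math.inf:
            best[target] = tmin
    return best


class TestWalkModel:
    def test_default_cutoff_is_12_5_minutes(self):
        m = WalkModel(speed=1.0, radius=750.0)
        assert m.cutoff_s == 750.0
        assert m.cutoff_min == 12.5

    def test_cutoff_tracks_radius_over_speed(self):
        m = WalkModel(speed=1.25, radius=1000.0)
        assert m.cutoff_s == pytest.approx(800.0)

    @pytest.mark.parametrize("speed,radius", [(0.0, 750.0), (1.0, 0.0), (-1, 100)])
    def test_nonpositive_parameters_rejected(self, speed, radius):
        with pytest.raises(ValueError):
            WalkModel(speed=speed, radius=radius)


class TestSnap:
    def test_facility_on_node_snaps_with_zero_offset(self):
        net = path_network([100.0, 100.0])
        pos = snap_facility(net, Facility("F1", Point(0.0, 0.0)))
        assert pos.offset_m == pytest.approx(0.0)
        assert (pos.u, pos.v) == (0, 1)
        assert pos.snap_dist_m == pytest.approx(0.0)

    def test_mid_edge_perpendicular_foot(self):
        net = path_network([100.0])
        pos = snap_facility(net, Facility("F1", Point(50.0, 5.0)))
        assert pos.offset_m == pytest.approx(50.0)
        assert pos.snap_dist_m == pytest.approx(5.0)
        assert pos.point.equals(Point(50.0, 0.0))

    def test_beyond_tolerance_is_error_naming_facility(self):
        net = path_network([100.0])
        with pytest.raises(ValueError, match="F9"):
            snap_facility(net, Facility("F9", Point(50.0, 500.0)), max_tol=200.0)

    def test_tie_broken_by_lowest_edge_id(self):
        # a square: point at centre is equidistant from all four edges
        net = RoadNetwork()
        for i, (x, y) in enumerate([(0, 0), (100, 0), (100, 100), (0, 100)]):
            net.add_node(i, x, y)
        for u, v in [(0, 1), (1, 2), (2, 3), (0, 3)]:
            net.add_edge(u, v)
        pos = snap_facility(net, Facility("F1", Point(50.0, 50.0)))
        assert (pos.u, pos.v) == (0, 1)


class TestServiceArea:
    def test_hand_dijkstra_on_path_graph(self):
        """A-B-C with 400 m edges, cutoff 750 s: B reached, B-C covered 350 m."""
        net = path_network([400.0, 400.0])
        pos = snap_facility(net, Facility("F1", Point(0.0, 0.0)))
        sa = service_area(net, pos, WalkModel(1.0, 750.0))
        assert sa.node_times[1] == pytest.approx(400.0)
        assert 2 not in sa.node_times
        assert sa.reached[(1, 2)] == [(0.0, pytest.approx(350.0))]
        assert sa.reached[(0, 1)] == [(0.0, 400.0)]

    def test_zero_cutoff_degenerates_to_snap_buffer(self):
        net = path_network([400.0])
        pos = snap_facility(net, Facility("F1", Point(100.0, 0.0)))
        sa = service_area(net, pos, WalkModel(1.0, 750.0), cutoff_s=0.0,
                          buffer_width=50.0)
        disc = pos.point.buffer(50.0)
        assert sa.polygon.symmetric_difference(disc).area < 1e-6 * disc.area
        assert sa.reached == {}

    def test_interior_snap_covers_both_directions(self):
        """Snapping mid-edge covers the edge symmetrically around the foot."""
        net = path_network([1000.0])
        pos = snap_facility(net, Facility("F1", Point(500.0, 10.0)))
        sa = service_area(net, pos, WalkModel(1.0, 200.0))
        assert sa.reached[(0, 1)] == [(pytest.approx(300.0), pytest.approx(700.0))]

    def test_monotone_in_cutoff(self):
        net = path_network([300.0, 300.0, 300.0])
        pos = snap_facility(net, Facility("F1", Point(0.0, 0.0)))
        small = service_area(net, pos, WalkModel(1.0, 500.0))
        large = service_area(net, pos, WalkModel(1.0, 750.0))
        assert small.polygon.difference(large.polygon).area < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reach_times_match_exhaustive_enumeration(self, seed, small_city):
        """Dijkstra node times equal the all-simple-paths oracle on a subgraph."""
        rng = np.random.default_rng(seed)
        g = small_city.roads.graph
        nodes = sorted(g.nodes)[:12]  # small connected corner of the grid
        sub = g.subgraph(nodes)
        net = RoadNetwork()
        net.graph = nx.Graph(sub)
        assert net.is_connected()
        src = int(rng.choice(nodes))
        x, y = net.node_xy(src)
        pos = snap_facility(net, Facility("F", Point(x, y)))
        sa = service_area(net, pos, WalkModel(1.0, 600.0))
        oracle = exhaustive_reach_times(net, src)
        expected = {n: t for n, t in oracle.items() if t <= 600.0}
        assert set(sa.node_times) == set(expected)
        for n, t in expected.items():
            assert sa.node_times[n] == pytest.approx(t, abs=1e-9)


class TestUnion:
    def _area(self, poly, fid="F"):
        from spatialaccess.network_access import ServiceArea
        return ServiceArea(fid, 0.0, {}, {}, poly, None)

    def test_single_area_is_itself(self):
        p = Point(0, 0).buffer(10)
        assert union_service_areas([self._area(p)]).equals(p)

    def test_disjoint_areas_sum(self):
        a = Point(0, 0).buffer(10)
        b = Point(1000, 0).buffer(10)
        u = union_service_areas([self._area(a), self._area(b)])
        assert u.area == pytest.approx(a.area + b.area)

    def test_duplicate_facility_idempotent(self):
        a = Point(0, 0).buffer(10)
        u1 = union_service_areas([self._area(a)])
        u2 = union_service_areas([self._area(a), self._area(a)])
        assert u1.equals(u2)

    def test_euclidean_baseline_is_disc_union(self):
        facs = [Facility("A", Point(0, 0)), Facility("B", Point(5000, 0))]
        cov = euclidean_coverage(facs, 750.0)
        # shapely buffers are 64-gon approximations: area deficit ~ 0.16%
        assert cov.area == pytest.approx(2 * math.pi * 750.0 ** 2, rel=5e-3)


def _block(bid, geom, per_stratum=10):
    return CensusBlock(bid, geom, {s: per_stratum for s in STRATA})


class TestOverlay:
    def test_block_inside_coverage_full_access(self):
        cov = box(-10, -10, 110, 110)
        fr = population_with_access([_block("B1", box(0, 0, 100, 100))], cov)
        assert fr["B1"] == pytest.approx(1.0)

    def test_half_covered_block_splits_areally(self):
        cov = box(0, 0, 50, 100)
        fr = population_with_access([_block("B1", box(0, 0, 100, 100))], cov)
        assert fr["B1"] == pytest.approx(0.5)

    def test_disjoint_block_no_access(self):
        cov = box(1000, 1000, 1100, 1100)
        fr = population_with_access([_block("B1", box(0, 0, 100, 100))], cov)
        assert fr["B1"] == 0.0

    def test_centroid_method_all_or_nothing(self):
        cov = box(0, 0, 51, 100)  # centroid (50, 50) inside
        blocks = [_block("B1", box(0, 0, 100, 100))]
        assert population_with_access(blocks, cov, "centroid")["B1"] == 1.0
        cov2 = box(0, 0, 49, 100)
        assert population_with_access(blocks, cov2, "centroid")["B1"] == 0.0


class TestTabulation:
    def test_headline_percentages_from_wave_totals(self):
        """Totals of 252897 with 136620 lacking access give 54.02% no-access."""
        # single fully-counted stratum carrying the wave totals
        tot = {s: 0 for s in STRATA}
        acc = {s: 0 for s in STRATA}
        tot["male_15_64"] = 252897
        acc["male_15_64"] = 252897 - 136620
        t = AccessTable.from_counts(acc, tot, year=1996)
        assert t.no_access_pct("total") == 54.02
        assert t.access_pct("total") == 45.98

    def test_half_covered_square_splits_counts(self):
        blocks = [_block("B1", box(0, 0, 100, 100), per_stratum=100)]
        fr = {"B1": 0.5}
        t = tabulate_access(fr, blocks)
        for s in STRATA:
            assert t.access[s] == 50
            assert t.no_access[s] == 50

    def test_conservation_per_cell(self, small_city):
        rng = np.random.default_rng(0)
        fr = {b.block_id: float(rng.uniform()) for b in small_city.blocks}
        t = tabulate_access(fr, small_city.blocks)
        for cell in AccessTable.CELLS:
            assert t.access[cell] + t.no_access[cell] == t.total[cell]
        assert t.total["total"] == sum(b.total for b in small_city.blocks)

    def test_all_covered_means_zero_no_access(self, small_city):
        fr = {b.block_id: 1.0 for b in small_city.blocks}
        t = tabulate_access(fr, small_city.blocks)
        for cell in AccessTable.CELLS:
            assert t.no_access_pct(cell) in (0.0, None)

    def test_zero_population_reports_na(self):
        blocks = [CensusBlock("B1", box(0, 0, 10, 10), {s: 0 for s in STRATA})]
        t = tabulate_access({"B1": 1.0}, blocks)
        assert t.access_pct("total") is None

    def test_pct_pairs_sum_to_100(self, small_city):
        rng = np.random.default_rng(1)
        fr = {b.block_id: float(rng.uniform()) for b in small_city.blocks}
        t = tabulate_access(fr, small_city.blocks)
        for cell in AccessTable.CELLS:
            if t.total[cell]:
                assert t.access_pct(cell) + t.no_access_pct(cell) == \
                    pytest.approx(100.0, abs=0.02)

    def test_pct_rounding_exact_at_half_boundary(self):
        """A true percentage of exactly x.xx5 rounds up, immune to float error."""
        assert pct_half_up(51085, 100000) == 51.09
        assert pct_half_up(510849, 1000000) == 51.08

    def test_largest_remainder_sums_exactly(self):
        out = largest_remainder([1.4, 2.4, 3.2], 7)
        assert sum(out) == 7
        assert out == [2, 2, 3]  # tie on .4 broken by index
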