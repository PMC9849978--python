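"""Unit and property tests for ANN, spatial weights, Moran's I and KDE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialaccess.spatial_patterns import (
    WeightScheme,
    bandwidth_rule,
    build_weights,
    kde_bandwidth,
    kernel_density,
    morans_i,
    nearest_neighbor_stat,
)

from conftest import brute_force_ann_dobs, brute_force_moran, grid_polys


class TestNearestNeighbor:
    def test_unit_square_corners_hand_values(self):
        """Four corners of a 1 m square with A = 1 m^2, evaluated by hand."""
        r = nearest_neighbor_stat([(0, 0), (1, 0), (0, 1), (1, 1)], area=1.0)
        assert r.d_obs == pytest.approx(1.0)
        assert r.d_exp == pytest.approx(0.25)
        assert r.ann == pytest.approx(4.0)
        assert r.se == pytest.approx(0.06534)
        assert r.z == pytest.approx(11.478, abs=1e-3)
        assert r.area_source == "user"

    def test_coincident_points_give_zero_ratio(self):
        r = nearest_neighbor_stat([(5.0, 5.0), (5.0, 5.0)], area=1.0)
        assert r.d_obs == 0.0
        assert r.ann == 0.0

    def test_default_area_is_enclosing_rectangle(self):
        r = nearest_neighbor_stat([(0, 0), (2, 0), (0, 3), (2, 3)])
        assert r.area == pytest.approx(6.0)
        assert r.area_source == "min_enclosing_rect"

    def test_degenerate_rectangle_requires_user_area(self):
        with pytest.raises(ValueError, match="area"):
            nearest_neighbor_stat([(0, 0), (0, 1), (0, 2)])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            nearest_neighbor_stat([(0, 0)], area=1.0)

    @pytest.mark.parametrize("n,seed", [(10, 0), (200, 1), (500, 2)])
    def test_matches_brute_force_scan(self, n, seed):
        """d_obs equals the O(n^2) nearest-neighbour scan."""
        pts = np.random.default_rng(seed).uniform(0, 1000, (n, 2))
        r = nearest_neighbor_stat(pts, area=1e6)
        assert r.d_obs == pytest.approx(brute_force_ann_dobs(pts), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ratio_and_z_consistent(self, seed):
        """ann = d_obs/d_exp and z = (d_obs - d_exp)/se for random inputs."""
        pts = np.random.default_rng(seed).uniform(0, 100, (20, 2))
        r = nearest_neighbor_stat(pts, area=1e4)
        assert r.ann == pytest.approx(r.d_obs / r.d_exp)
        assert r.z == pytest.approx((r.d_obs - r.d_exp) / r.se)

    def test_csr_null_mean_near_one(self):
        """Mean ratio over CSR draws sits near 1 (small positive edge bias)."""
        anns = []
        for s in range(50):
            pts = np.random.default_rng(s).uniform(0, 1000, (500, 2))
            anns.append(nearest_neighbor_stat(pts, area=1e6).ann)
        assert np.mean(anns) == pytest.approx(1.0, abs=0.05)


class TestWeights:
    def test_rook_2x2_grid(self, unit_grid_polys):
        """Each cell of a 2x2 grid has exactly 2 rook neighbours; s0 = 8."""
        w = build_weights(unit_grid_polys, WeightScheme.ROOK)
        assert w.s0 == pytest.approx(8.0)
        row_counts = np.asarray((w.matrix > 0).sum(axis=1)).ravel()
        assert list(row_counts) == [2, 2, 2, 2]
        assert (abs(w.matrix - w.matrix.T)).sum() == 0  # symmetric

    def test_inverse_distance_pair(self):
        w = build_weights([(0.0, 0.0), (10.0, 0.0)], "inverse_distance", cutoff=20.0)
        assert w.matrix[0, 1] == pytest.approx(0.1)
        assert w.matrix[1, 0] == pytest.approx(0.1)

    def test_diagonal_always_zero(self):
        pts = np.random.default_rng(0).uniform(0, 10, (8, 2))
        w = build_weights(pts, "knn", k=3)
        assert w.matrix.diagonal().sum() == 0

    @pytest.mark.parametrize("scheme,kwargs", [
        ("inverse_distance", {}),
        ("distance_band", {"cutoff": 5.0}),
        ("knn", {"k": 2}),
    ])
    def test_row_standardization(self, scheme, kwargs):
        pts = np.random.default_rng(1).uniform(0, 10, (9, 2))
        w = build_weights(pts, scheme, row_standardize=True, **kwargs)
        rows = np.asarray(w.matrix.sum(axis=1)).ravel()
        assert rows == pytest.approx(np.ones(9), abs=1e-12)

    def test_isolated_feature_rejected(self):
        pts = [(0, 0), (1, 0), (100, 100)]
        with pytest.raises(ValueError, match="no neighbours"):
            build_weights(pts, "distance_band", cutoff=5.0)

    def test_default_cutoff_is_max_nn_distance(self):
        # collinear points 1 m apart except the last, 3 m away
        pts = [(0, 0), (1, 0), (2, 0), (5, 0)]
        w = build_weights(pts, "inverse_distance")
        # cutoff = 3 connects every pair within 3 m, incl. the far point
        assert w.matrix[3, 2] == pytest.approx(1 / 3)
        assert w.matrix[3, 0] == 0


class TestMoransI:
    def test_checkerboard_is_minus_one(self, unit_grid_polys):
        """Perfect alternation on a 2x2 rook grid gives I = -1 exactly."""
        w = build_weights(unit_grid_polys, "rook")
        r = morans_i([1.0, -1.0, -1.0, 1.0], w)
        assert r.i == pytest.approx(-1.0, abs=1e-12)
        assert r.e_i == pytest.approx(-1.0 / 3.0)
        assert r.z < 0

    def test_expected_value_n5(self):
        pts = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)]
        w = build_weights(pts, "distance_band", cutoff=1.5)
        r = morans_i([1.0, 2.0, 1.0, 3.0, 2.0], w)
        assert r.e_i == -0.25

    def test_constant_values_rejected(self, unit_grid_polys):
        w = build_weights(unit_grid_polys, "rook")
        with pytest.raises(ValueError, match="zero variance"):
            morans_i([2.0, 2.0, 2.0, 2.0], w)

    @pytest.mark.parametrize("n,scheme,kwargs,seed", [
        (25, "rook", {}, 0),
        (50, "inverse_distance", {}, 1),
        (100, "knn", {"k": 4}, 2),
    ])
    def test_matches_naive_double_sum(self, n, scheme, kwargs, seed):
        """I equals the brute-force double loop on dense weights."""
        rng = np.random.default_rng(seed)
        if scheme == "rook":
            side = int(math.isqrt(n))
            geoms = grid_polys(side, side)
            n = side * side
        else:
            geoms = rng.uniform(0, 100, (n, 2))
        vals = rng.normal(size=n)
        w = build_weights(geoms, scheme, **kwargs)
        r = morans_i(vals, w)
        assert r.i == pytest.approx(brute_force_moran(vals, w.matrix.toarray()),
                                    abs=1e-12)

    def test_null_distribution_centred_on_expectation(self):
        """i.i.d. values on a 10x10 rook grid: mean I over seeds near E[I]."""
        geoms = grid_polys(10, 10)
        w = build_weights(geoms, "rook")
        sims = []
        for s in range(200):
            vals = np.random.default_rng(s).normal(size=100)
            sims.append(morans_i(vals, w).i)
        se_mean = np.std(sims) / math.sqrt(len(sims))
        assert abs(np.mean(sims) - (-1 / 99)) < 3 * se_mean

    def test_permutation_p_small_for_checkerboard(self):
        """Strong alternation on a 4x4 grid is significant under permutation."""
        geoms = grid_polys(4, 4)
        vals = [(-1.0) ** (x + y) for y in range(4) for x in range(4)]
        w = build_weights(geoms, "rook")
        r1 = morans_i(vals, w, inference="permutation", n_perm=999, seed=42)
        r2 = morans_i(vals, w, inference="permutation", n_perm=999, seed=42)
        assert r1.p_perm < 0.1
        assert r1.p_perm == r2.p_perm  # reproducible under fixed seed

    def test_clustered_field_positive_significant(self):
        """Smooth gradient values are detected as positively autocorrelated."""
        geoms = grid_polys(8, 8)
        vals = [x + y for y in range(8) for x in range(8)]
        w = build_weights(geoms, "rook")
        r = morans_i(np.array(vals, float), w)
        assert r.i > 0
        assert r.z > 1.96


class TestKDE:
    def test_bandwidth_rule_hand_value(self):
        """SD=100, Dm=50, n=100: h = 0.9*min(100, 60.056)*0.39811 = 21.52."""
        assert bandwidth_rule(100.0, 50.0, 100) == pytest.approx(21.52, abs=0.01)

    def test_bandwidth_min_takes_dm_branch(self):
        # huge SD: the sqrt(1/ln 2)*Dm branch wins
        assert bandwidth_rule(1e6, 50.0, 100) == pytest.approx(
            0.9 * math.sqrt(1 / math.log(2)) * 50.0 * 100 ** -0.2)

    def test_bandwidth_n_exponent_scaling(self):
        """Duplicating every point scales h by 2^(-0.2)."""
        pts = np.random.default_rng(3).uniform(0, 100, (50, 2))
        h1 = kde_bandwidth(pts)
        h2 = kde_bandwidth(np.vstack([pts, pts]))
        assert h2 / h1 == pytest.approx(2 ** -0.2)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            kde_bandwidth([(1.0, 1.0), (1.0, 1.0)])

    def test_single_point_mass_conserved(self):
        """Numeric integral of one unit-weight kernel is 1 within 1%."""
        surf = kernel_density([(0.0, 0.0)], cell_size=5.0, bandwidth=100.0)
        assert surf.total_mass() == pytest.approx(1.0, rel=0.01)

    def test_weighted_mass_conserved(self):
        pts = np.random.default_rng(4).uniform(0, 500, (20, 2))
        w = np.random.default_rng(5).uniform(1, 10, 20)
        surf = kernel_density(pts, weights=w, cell_size=10.0, bandwidth=120.0)
        assert surf.total_mass() == pytest.approx(w.sum(), rel=0.01)

    def test_linearity_in_weights(self):
        pts = [(0.0, 0.0), (50.0, 20.0)]
        s1 = kernel_density(pts, weights=[1.0, 1.0], cell_size=4.0, bandwidth=40.0)
        s2 = kernel_density(pts, weights=[2.0, 2.0], cell_size=4.0, bandwidth=40.0)
        np.testing.assert_allclose(s2.values, 2 * s1.values, atol=1e-12)

    def test_compact_support_separates_far_points(self):
        """Two points 10h apart give two disjoint positive discs."""
        h = 10.0
        surf = kernel_density([(0.0, 0.0), (100.0, 0.0)], cell_size=1.0, bandwidth=h)
        # density vanishes midway between the points
        mid_ix = int((50.0 - surf.origin[0]) / surf.cell_size)
        assert surf.values[:, mid_ix].max() == 0.0
        assert surf.values.max() > 0.0

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            kernel_density([(0, 0), (1, 1)], weights=[1.0, 0.0], cell_size=1.0,
                           bandwidth=5.0)
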