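"""Point-pattern and spatial-autocorrelation statistics.

Three classical global statistics used to characterise urban facility and
deprivation patterns:

* **Average nearest neighbour (ANN)** — the ratio of the observed mean
  nearest-neighbour distance to its expectation under complete spatial
  randomness (CSR).  ANN < 1 indicates clustering, ANN > 1 dispersion;
  the z-score uses the CSR standard error 0.26136 / sqrt(n^2 / A).
* **Global Moran's I** — the cross-product statistic
  I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 over mean-deviations
  z_i, with E[I] = -1/(n-1), the normality-assumption closed-form
  variance, and an optional permutation test.
* **Kernel density** — a quartic (biweight) kernel surface with the
  search-radius rule h = 0.9 * min(SD, sqrt(1/ln 2) * Dm) * n^(-0.2),
  where SD is the standard distance of the points about their mean
  centre and Dm the median distance to the mean centre.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

__all__ = [
    "ANNResult",
    "SpatialWeights",
    "MoranResult",
    "KDESurface",
    "WeightScheme",
    "nearest_neighbor_stat",
    "build_weights",
    "morans_i",
    "bandwidth_rule",
    "kde_bandwidth",
    "kernel_density",
]

#: CSR standard-error constant for the ANN z-score.
_ANN_SE_CONST = 0.26136


@dataclass(frozen=True)
class ANNResult:
    """Average-nearest-neighbour test result (distances in metres)."""

    d_obs: float
    d_exp: float
    ann: float
    se: float
    z: float
    n: int
    area: float
    area_source: str  # "min_enclosing_rect" | "user"

    def as_dict(self) -> dict:
        return {
            "statistic": "ann", "d_obs": self.d_obs, "d_exp": self.d_exp,
            "ann": self.ann, "se": self.se, "z": self.z, "n": self.n,
            "area": self.area, "area_source": self.area_source,
        }


def _as_points(points) -> np.ndarray:
    if len(points) and isinstance(points[0], Point):
        arr = np.array([[p.x, p.y] for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar coordinates")
    if not np.isfinite(arr).all():
        raise ValueError("points contain non-finite coordinates")
    return arr


def nearest_neighbor_stat(points, area: float | None = None) -> ANNResult:
    """Average nearest neighbour ratio with CSR z-score.

    Parameters
    ----------
    points : sequence of (x, y) or shapely Points
        At least two planar points in metres.
    area : float, optional
        Study area A in square metres.  When omitted, the area of the
        axis-aligned minimum enclosing rectangle of the points is used.

    Notes
    -----
    d_obs is the mean distance from each point to its nearest *other*
    point (coincident points give distance 0); d_exp = 0.5 / sqrt(n / A);
    se = 0.26136 / sqrt(n^2 / A); z = (d_obs - d_exp) / se.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError("nearest_neighbor_stat requires at least 2 points")
    if area is None:
        xmin, ymin = pts.min(axis=0)
        xmax, ymax = pts.max(axis=0)
        area = float((xmax - xmin) * (ymax - ymin))
        area_source = "min_enclosing_rect"
        if area <= 0:
            raise ValueError(
                "degenerate minimum enclosing rectangle (zero area); "
                "supply the study area explicitly")
    else:
        area = float(area)
        area_source = "user"
        if area <= 0:
            raise ValueError("area must be positive")

    tree = cKDTree(pts)
    # k=2: nearest neighbour other than the point itself; coincident
    # points legitimately yield d_i = 0.
    dists, _ = tree.query(pts, k=2)
    d_obs = float(dists[:, 1].mean())
    d_exp = 0.5 / math.sqrt(n / area)
    se = _ANN_SE_CONST / math.sqrt(n * n / area)
    return ANNResult(
        d_obs=d_obs, d_exp=d_exp, ann=d_obs / d_exp, se=se,
        z=(d_obs - d_exp) / se, n=n, area=area, area_source=area_source,
    )


# ---------------------------------------------------------------------------
# spatial weights

class WeightScheme(str, enum.Enum):
    INVERSE_DISTANCE = "inverse_distance"
    DISTANCE_BAND = "distance_band"
    KNN = "knn"
    ROOK = "rook"


@dataclass
class SpatialWeights:
    """A sparse spatial-weights matrix with zero diagonal.

    ``matrix`` is an (n, n) CSR sparse matrix; ``s0`` is the grand sum of
    all weights.  Row standardization rescales each nonzero row to sum
    to one.
    """

    matrix: sparse.csr_matrix
    scheme: WeightScheme
    row_standardized: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())


def _centroids(geoms) -> np.ndarray:
    out = []
    for g in geoms:
        if isinstance(g, (Point,)):
            out.append((g.x, g.y))
        elif isinstance(g, Polygon):
            c = g.centroid
            out.append((c.x, c.y))
        else:
            out.append(tuple(np.asarray(g, dtype=float)))
    return np.asarray(out, dtype=float)


def build_weights(geoms, scheme: WeightScheme | str = WeightScheme.INVERSE_DISTANCE,
                  *, cutoff: float | None = None, k: int | None = None,
                  row_standardize: bool = False) -> SpatialWeights:
    """Construct spatial weights from points or polygons.

    Schemes
    -------
    inverse_distance
        w_ij = 1/d_ij for d_ij <= cutoff (cutoff defaults to the maximum
        nearest-neighbour distance, so no feature is isolated).
    distance_band
        binary w_ij = 1 for d_ij <= cutoff (cutoff required).
    knn
        binary k-nearest-neighbour weights; may be asymmetric.
    rook
        shared-boundary adjacency for polygons (boundary intersection of
        positive length).

    Polygons are reduced to centroids except under ``rook``.
    """
    scheme = WeightScheme(scheme)
    n = len(geoms)
    if n < 2:
        raise ValueError("need at least 2 features to build weights")

    if scheme is WeightScheme.ROOK:
        polys = list(geoms)
        if not all(isinstance(g, Polygon) for g in polys):
            raise ValueError("rook adjacency requires polygon geometries")
        rows, cols, vals = [], [], []
        # O(n^2) boundary test; adequate for block-level analyses
        for i in range(n):
            for j in range(i + 1, n):
                inter = polys[i].boundary.intersection(polys[j].boundary)
                if inter.length > 0:
                    rows += [i, j]
                    cols += [j, i]
                    vals += [1.0, 1.0]
        mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    else:
        pts = _centroids(geoms)
        tree = cKDTree(pts)
        if scheme is WeightScheme.KNN:
            if k is None:
                raise ValueError("knn scheme requires k")
            dists, idx = tree.query(pts, k=k + 1)
            rows = np.repeat(np.arange(n), k)
            cols = idx[:, 1:].ravel()
            vals = np.ones(n * k)
            mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        else:
            if cutoff is None:
                if scheme is WeightScheme.DISTANCE_BAND:
                    raise ValueError("distance_band scheme requires a cutoff")
                nn_d, _ = tree.query(pts, k=2)
                cutoff = float(nn_d[:, 1].max())
            pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
            if scheme is WeightScheme.DISTANCE_BAND:
                vals = np.ones(len(pairs))
            else:
                d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
                if np.any(d == 0):
                    raise ValueError("coincident features under inverse_distance weights")
                vals = 1.0 / d
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
            mat = sparse.csr_matrix((np.concatenate([vals, vals]), (rows, cols)),
                                    shape=(n, n))

    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    isolated = np.flatnonzero(row_sums == 0)
    if isolated.size:
        raise ValueError(f"features with no neighbours under {scheme.value}: "
                         f"{isolated[:10].tolist()}")
    if row_standardize:
        inv = sparse.diags(1.0 / row_sums)
        mat = sparse.csr_matrix(inv @ mat)
    mat.setdiag(0.0)
    mat.eliminate_zeros()
    return SpatialWeights(matrix=mat, scheme=scheme, row_standardized=row_standardize)


# ---------------------------------------------------------------------------
# Moran's I

@dataclass(frozen=True)
class MoranResult:
    """Global Moran's I with analytic (normality) and optional permutation inference."""

    i: float
    e_i: float
    v_i: float
    z: float
    p_analytic: float
    p_perm: float | None
    n_perm: int
    seed: int | None
    n: int


def morans_i(values, w: SpatialWeights, inference: str = "normal",
             n_perm: int = 999, seed: int | None = None) -> MoranResult:
    """Global Moran's I of per-feature values under spatial weights ``w``.

    ``inference='normal'`` uses the normality-assumption closed-form
    variance; ``inference='permutation'`` additionally computes a
    two-sided pseudo p-value over ``n_perm`` random relabelings.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) != w.n:
        raise ValueError("values length must match the weights matrix")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance, I undefined")
    n = len(x)
    W = w.matrix
    s0 = w.s0
    i_obs = (n / s0) * float(z @ (W @ z)) / denom

    e_i = -1.0 / (n - 1)
    # normality-assumption variance: needs S1 = 0.5*sum (w_ij + w_ji)^2 and
    # S2 = sum_i (row_i + col_i)^2
    Wd = W + W.T
    s1 = 0.5 * float(Wd.multiply(Wd).sum())
    rc = np.asarray(W.sum(axis=1)).ravel() + np.asarray(W.sum(axis=0)).ravel()
    s2 = float(rc @ rc)
    v_i = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i ** 2
    if v_i <= 0:
        raise ValueError("nonpositive Moran variance; weights degenerate")
    z_score = (i_obs - e_i) / math.sqrt(v_i)
    from scipy.stats import norm
    p_analytic = 2.0 * float(norm.sf(abs(z_score)))

    p_perm = None
    if inference == "permutation":
        rng = np.random.default_rng(seed)
        count_ge = 0
        count_le = 0
        for _ in range(n_perm):
            zp = rng.permutation(z)
            i_p = (n / s0) * float(zp @ (W @ zp)) / denom
            if i_p >= i_obs:
                count_ge += 1
            if i_p <= i_obs:
                count_le += 1
        p_one = (min(count_ge, count_le) + 1) / (n_perm + 1)
        p_perm = min(1.0, 2.0 * p_one)
    elif inference != "normal":
        raise ValueError(f"unknown inference {inference!r}")

    return MoranResult(i=i_obs, e_i=e_i, v_i=v_i, z=z_score,
                       p_analytic=p_analytic, p_perm=p_perm,
                       n_perm=n_perm if inference == "permutation" else 0,
                       seed=seed, n=n)


# ---------------------------------------------------------------------------
# kernel density

@dataclass
class KDESurface:
    """A raster density surface (row 0 = southernmost row).

    ``values[iy, ix]`` is the density (weight per square metre) at the
    centre of the cell whose lower-left corner is
    ``(origin[0] + ix*cell_size, origin[1] + iy*cell_size)``.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    bandwidth: float
    bandwidth_source: str  # "rule" | "user"

    def total_mass(self) -> float:
        """Numeric integral of the surface (density x cell area)."""
        return float(self.values.sum() * self.cell_size ** 2)

    def peak_cell(self) -> tuple[int, int]:
        """(iy, ix) of the maximum-density cell (first by row-major order)."""
        iy, ix = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(iy), int(ix)

    def peak_xy(self) -> tuple[float, float]:
        iy, ix = self.peak_cell()
        return (self.origin[0] + (ix + 0.5) * self.cell_size,
                self.origin[1] + (iy + 0.5) * self.cell_size)

    def to_ascii_grid(self, path) -> None:
        """Write as an ESRI ASCII grid (rows north to south)."""
        ny, nx = self.values.shape
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"ncols {nx}\nnrows {ny}\n")
            fh.write(f"xllcorner {self.origin[0]}\nyllcorner {self.origin[1]}\n")
            fh.write(f"cellsize {self.cell_size}\nNODATA_value -9999\n")
            for row in self.values[::-1]:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def _weighted_points(points, weights) -> tuple[np.ndarray, np.ndarray]:
    pts = _as_points(points)
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(pts),):
            raise ValueError("weights must match points")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    return pts, w


def bandwidth_rule(sd: float, dm: float, n: float) -> float:
    """Search-radius rule h = 0.9 * min(SD, sqrt(1/ln 2) * Dm) * n^(-0.2)."""
    if sd <= 0 or n <= 0:
        raise ValueError("sd and n must be positive")
    return 0.9 * min(sd, math.sqrt(1.0 / math.log(2.0)) * dm) * float(n) ** -0.2


def kde_bandwidth(points, weights=None) -> float:
    """Default kernel search radius from the point distribution.

    h = 0.9 * min(SD, sqrt(1/ln 2) * Dm) * n^(-0.2), where SD is the
    (weighted) standard distance about the mean centre, Dm the weighted
    median distance to the mean centre, and n the total point weight.
    """
    pts, w = _weighted_points(points, weights)
    if len(pts) < 2:
        raise ValueError("kde_bandwidth requires at least 2 points")
    wsum = w.sum()
    centre = (pts * w[:, None]).sum(axis=0) / wsum
    d = np.linalg.norm(pts - centre, axis=1)
    sd = math.sqrt(float((w * d ** 2).sum() / wsum))
    if sd == 0:
        raise ValueError("all points coincident: zero standard distance")
    # weighted median of distances
    order = np.argsort(d)
    cum = np.cumsum(w[order])
    dm = float(d[order][np.searchsorted(cum, 0.5 * wsum)])
    h = bandwidth_rule(sd, dm, float(wsum))
    if h <= 0:
        raise ValueError("degenerate bandwidth (collinear/coincident points); "
                         "supply a bandwidth explicitly")
    return h


def kernel_density(points, weights=None, cell_size: float = None,
                   bandwidth: float | None = None,
                   extent: tuple[float, float, float, float] | None = None) -> KDESurface:
    """Quartic-kernel density surface of weighted points.

    Each point contributes a compact-support quartic (biweight) kernel
    K(d) = (3 / (pi h^2)) * (1 - d^2/h^2)^2 for d < h, scaled by its
    weight, so the surface integrates to the total point weight.
    """
    pts, w = _weighted_points(points, weights)
    if cell_size is None or cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if bandwidth is None:
        h = kde_bandwidth(pts, w)
        source = "rule"
    else:
        h = float(bandwidth)
        source = "user"
        if h <= 0:
            raise ValueError("bandwidth must be positive")

    if extent is None:
        xmin, ymin = pts.min(axis=0) - h
        xmax, ymax = pts.max(axis=0) + h
    else:
        xmin, ymin, xmax, ymax = extent
    nx = max(1, int(math.ceil((xmax - xmin) / cell_size)))
    ny = max(1, int(math.ceil((ymax - ymin) / cell_size)))
    xc = xmin + (np.arange(nx) + 0.5) * cell_size
    yc = ymin + (np.arange(ny) + 0.5) * cell_size

    values = np.zeros((ny, nx))
    norm_c = 3.0 / (math.pi * h * h)
    for (px, py), wt in zip(pts, w):
        ix0 = max(0, int((px - h - xmin) / cell_size) - 1)
        ix1 = min(nx, int((px + h - xmin) / cell_size) + 2)
        iy0 = max(0, int((py - h - ymin) / cell_size) - 1)
        iy1 = min(ny, int((py + h - ymin) / cell_size) + 2)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        dx = xc[ix0:ix1] - px
        dy = yc[iy0:iy1] - py
        d2 = (dy[:, None] ** 2 + dx[None, :] ** 2) / (h * h)
        mask = d2 < 1.0
        contrib = np.where(mask, wt * norm_c * (1.0 - d2) ** 2, 0.0)
        values[iy0:iy1, ix0:ix1] += contrib

    return KDESurface(origin=(float(xmin), float(ymin)), cell_size=float(cell_size),
                      values=values, bandwidth=h, bandwidth_source=source)
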