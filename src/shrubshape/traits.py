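"""Size-related traits of a clean bush cloud.

Height, in-row width (WIR, along x), across-row width (WAR, along y),
convex- and concave-hull canopy volumes, and the crown size: the bush's
across-row diameter 15 cm above the stem base, where an over-the-row
harvester's catch plates meet the plant.

Crown measurement is a three-step chain: slice a thin horizontal slab of
points at crown height, discard far-from-center stragglers with a distance
histogram, then fit the smallest axis-aligned ellipse that still covers a
target fraction of the retained points. The ellipse's across-row (y)
diameter is the crown size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .io import PointCloud

__all__ = [
    "SizeTraits",
    "CrownConfig",
    "CrownFit",
    "bush_dimensions",
    "hull_volumes",
    "crown_cross_section",
    "crown_filter",
    "crown_ellipse",
    "measure_crown",
    "measure_size_traits",
]


@dataclass
class SizeTraits:
    height_m: float
    wir_m: float
    war_m: float
    volume_convex_m3: float
    volume_concave_m3: float
    crown_m: float

    def as_row(self) -> dict:
        return {
            "height_m": self.height_m, "wir_m": self.wir_m,
            "war_m": self.war_m, "vol_convex_m3": self.volume_convex_m3,
            "vol_concave_m3": self.volume_concave_m3, "crown_m": self.crown_m,
        }


@dataclass
class CrownConfig:
    """Crown-measurement parameters.

    ``crown_height_m``: measurement height above the bush's minimum z
    (0.15 m — catch-plate height). ``dist_bin_m``: distance-histogram bin
    width. ``retain_percentile``: percentile of first-cluster distances used
    as the straggler cut. ``coverage``: required fraction of retained points
    inside the fitted ellipse. ``grid_m``: lattice spacing of the exact
    diameter search.
    """

    crown_height_m: float = 0.15
    slab_half_thickness_m: float = 0.01
    dist_bin_m: float = 0.05
    retain_percentile: float = 95.0
    coverage: float = 0.9
    grid_m: float = 0.001
    concave_alpha: float = 1.0   # inverse circumradius cutoff, 1/m

    def __post_init__(self):
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")
        if not (0 < self.retain_percentile <= 100):
            raise ValueError("retain_percentile must be in (0, 100]")


@dataclass
class CrownFit:
    """Fitted crown ellipse; ``crown_m`` is the vertical (y) diameter."""

    cross_section_points: np.ndarray   # (N, 2) slab points in the x-y plane
    retained_points: np.ndarray        # survivors of the distance filter
    center: np.ndarray                 # (2,) ellipse center
    d_x: float                         # in-row diameter, m
    d_y: float                         # across-row diameter = crown size, m
    coverage_achieved: float

    @property
    def crown_m(self) -> float:
        return self.d_y

    def summary(self) -> str:
        return (
            f"CrownFit: d_x={self.d_x:.3f} m, d_y(crown)={self.d_y:.3f} m, "
            f"coverage={self.coverage_achieved:.2f} "
            f"({len(self.retained_points)}/{len(self.cross_section_points)} "
            "points retained)"
        )


def bush_dimensions(cloud: PointCloud) -> tuple[float, float, float]:
    """(height, WIR, WAR) = coordinate extents along z, x, y."""
    pts = cloud.points
    ext = pts.max(axis=0) - pts.min(axis=0)
    return float(ext[2]), float(ext[0]), float(ext[1])


def _alpha_shape_volume(points: np.ndarray, alpha: float) -> float:
    """Concave (alpha-shape) volume: summed volume of Delaunay tetrahedra
    whose circumradius is below 1/alpha."""
    tri = Delaunay(points)
    simplices = points[tri.simplices]          # (M, 4, 3)
    a, b, c, d = (simplices[:, i, :] for i in range(4))
    vol6 = np.einsum("ij,ij->i", a - d, np.cross(b - d, c - d))
    vols = np.abs(vol6) / 6.0
    # circumradius R = |PA| |PB| |PC| ... via the Cayley-Menger-free formula:
    # R = |a'|·|b'|·|c'| style is 2D; use linear solve for circumcenters.
    rows = np.stack([b - a, c - a, d - a], axis=1)           # (M, 3, 3)
    rhs = 0.5 * np.einsum("ijk,ijk->ij", rows, rows)          # (M, 3)
    ok = np.abs(np.linalg.det(rows)) > 1e-14
    radii = np.full(len(vols), np.inf)
    if ok.any():
        centers = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    keep = radii <= 1.0 / alpha
    return float(vols[keep].sum())


def hull_volumes(cloud: PointCloud,
                 concave_alpha: float = 1.0) -> tuple[float, float]:
    """(convex, concave) hull volumes in m³.

    The concave volume is an alpha-shape volume (Delaunay tetrahedra with
    circumradius <= 1/``concave_alpha``), so convex >= concave always.
    Degenerate (coplanar) clouds return (0, 0) with a warning.
    """
    pts = cloud.points
    try:
        convex = float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate (coplanar) cloud; hull volumes set to 0")
        return 0.0, 0.0
    concave = _alpha_shape_volume(pts, concave_alpha)
    return convex, min(concave, convex)


def crown_cross_section(cloud: PointCloud,
                        cfg: CrownConfig | None = None) -> np.ndarray:
    """Slab of points at crown height, projected to the x-y plane."""
    cfg = cfg or CrownConfig()
    z = cloud.points[:, 2]
    z_target = z.min() + cfg.crown_height_m
    sel = np.abs(z - z_target) <= cfg.slab_half_thickness_m
    if not sel.any():
        raise ValueError(
            f"no points within {cfg.slab_half_thickness_m} m of crown height "
            f"{cfg.crown_height_m} m above the bush base"
        )
    return cloud.points[sel][:, :2].copy()


def crown_filter(points: np.ndarray,
                 cfg: CrownConfig | None = None) -> np.ndarray:
    """Distance-histogram filter isolating the crown's own cross-section.

    Distances to the componentwise-median center are histogrammed at
    ``dist_bin_m``; bins are grouped into clusters split at local minima (a
    bin smaller than both neighbours). The first cluster is the crown —
    branches and, for leaning bushes, displaced canopy fall in farther
    clusters — the ``retain_percentile`` of first-cluster distances is the
    cut. A histogram with no local minimum is a single compact cluster and
    is retained whole.
    """
    cfg = cfg or CrownConfig()
    points = np.asarray(points, dtype=float)
    center = np.median(points, axis=0)
    dist = np.linalg.norm(points - center, axis=1)
    n_bins = max(int(np.ceil(dist.max() / cfg.dist_bin_m)), 1)
    counts, edges = np.histogram(dist, bins=n_bins,
                                 range=(0.0, n_bins * cfg.dist_bin_m))
    split = _first_local_minimum_edge(counts)
    if split is None:
        return points   # single cluster: nothing to cut away
    in_first = dist < edges[split]
    if not in_first.any():
        return points
    cut = np.percentile(dist[in_first], cfg.retain_percentile)
    return points[in_first & (dist <= cut)]


def _first_local_minimum_edge(counts: np.ndarray):
    """Edge index of the first local-minimum bin (run-aware).

    A maximal run of equal bin values lower than the bins on both sides is
    one local minimum — this covers the common case of empty-bin plateaus
    between well-separated clusters. Returns the edge index at the run's
    center, or None when the histogram is unimodal.
    """
    counts = np.asarray(counts)
    runs = []
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            runs.append((counts[start], start, i - 1))
            start = i
    for j in range(1, len(runs) - 1):
        val, lo, hi = runs[j]
        if val < runs[j - 1][0] and val < runs[j + 1][0]:
            return (lo + hi + 2) // 2
    return None


def _min_feasible_dy(px: np.ndarray, py: np.ndarray, d_x: float,
                     k: int) -> float:
    """Smallest d_y such that >= k points satisfy the ellipse membership
    (2 p_x / d_x)² + (2 p_y / d_y)² <= 1."""
    u = (2.0 * px / d_x) ** 2
    inside_x = u < 1.0
    if inside_x.sum() < k:
        return np.inf
    need = np.full(len(px), np.inf)
    need[inside_x] = (2.0 * py[inside_x]) ** 2 / (1.0 - u[inside_x])
    kth = np.partition(need, k - 1)[k - 1]
    return float(np.sqrt(kth)) if np.isfinite(kth) else np.inf


def crown_ellipse(retained: np.ndarray,
                  cfg: CrownConfig | None = None) -> CrownFit:
    """Smallest axis-aligned ellipse covering the target point fraction.

    Minimizes d_x + d_y subject to |covered| / |retained| >= coverage, where
    a point is covered when (p_x/(d_x/2))² + (p_y/(d_y/2))² <= 1 around the
    Gaussian-mean center. The optimum is found exactly: d_x is scanned over
    a ``grid_m`` lattice and, for each d_x, the minimal feasible d_y is the
    k-th order statistic of the per-point d_y requirement (rounded up to the
    lattice). Deterministic, no local optima.
    """
    cfg = cfg or CrownConfig()
    retained = np.asarray(retained, dtype=float)
    if len(retained) < 5:
        raise ValueError("need at least 5 retained points to fit an ellipse")
    center = retained.mean(axis=0)
    px = retained[:, 0] - center[0]
    py = retained[:, 1] - center[1]
    k = int(np.ceil(cfg.coverage * len(retained)))
    g = cfg.grid_m

    # the optimum can exceed the point extent (an ellipse through a corner
    # point (px, py) is smallest at semi-axes sqrt(2)*px, sqrt(2)*py)
    d_x_max = 2.0 * np.sqrt(2.0) * np.abs(px).max() + 2 * g
    d_x_grid = np.arange(g, d_x_max + g, g)
    best = (np.inf, np.nan, np.nan)
    for d_x in d_x_grid:
        d_y = _min_feasible_dy(px, py, d_x, k)
        if not np.isfinite(d_y):
            continue
        d_y = np.ceil(d_y / g - 1e-9) * g     # snap up: stays feasible
        obj = d_x + d_y
        if obj < best[0] - 1e-12:
            best = (obj, float(d_x), float(d_y))
    if not np.isfinite(best[0]):
        raise ValueError(
            "ellipse fit failed: no diameter pair reaches coverage "
            f"{cfg.coverage:.2f}"
        )
    _, d_x, d_y = best
    u = (2 * px / d_x) ** 2 + (2 * py / max(d_y, 1e-12)) ** 2
    achieved = float((u <= 1.0 + 1e-9).mean())
    return CrownFit(
        cross_section_points=retained, retained_points=retained,
        center=center, d_x=d_x, d_y=d_y, coverage_achieved=achieved,
    )


def measure_crown(cloud: PointCloud,
                  cfg: CrownConfig | None = None) -> CrownFit:
    """Crown size of a clean bush cloud: slab, filter, ellipse fit."""
    cfg = cfg or CrownConfig()
    section = crown_cross_section(cloud, cfg)
    retained = crown_filter(section, cfg) if len(section) >= 10 else section
    fit = crown_ellipse(retained, cfg)
    fit.cross_section_points = section
    return fit


def measure_size_traits(cloud: PointCloud,
                        cfg: CrownConfig | None = None) -> SizeTraits:
    """All size traits of one clean bush."""
    cfg = cfg or CrownConfig()
    height, wir, war = bush_dimensions(cloud)
    vol_cx, vol_cc = hull_volumes(cloud, cfg.concave_alpha)
    crown = measure_crown(cloud, cfg)
    return SizeTraits(height, wir, war, vol_cx, vol_cc, crown.crown_m)
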