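"""Field-scan preprocessing: alignment, segmentation, cleaning.

Turns a raw field point cloud into clean per-bush clouds:

1. rigid alignment — the ground plane (robust plane fit) is rotated parallel
   to the x-y plane and the planting rows (Hough transform on a depth
   raster) to the +x direction;
2. per-bush cropping with user-supplied boxes;
3. adaptive ground removal via a height-histogram gradient rule;
4. statistical outlier removal (SOR);
5. density-based clustering, keeping the largest cluster as the bush.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import hough_line, hough_line_peaks
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .io import BoundingBox, PointCloud, crop_box

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "AlignmentResult",
    "DepthRaster",
    "RowDetection",
    "HeightHistogram",
    "fit_ground_plane",
    "rasterize_depth",
    "detect_row_direction",
    "align_cloud",
    "segment_bushes",
    "height_histogram",
    "ground_threshold",
    "remove_ground",
    "sor_filter",
    "largest_cluster",
    "clean_bush",
]


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing stage.

    Defaults follow the published protocol: 0.3 m depth threshold for bush
    pixels, 0.01 m height-histogram bins with noise factor t = 5, SOR with
    k = 10 neighbours and n = 1 standard deviations, 0.5 m depth-raster
    cells. DBSCAN's radius/count and the plane-fit tolerance are not part of
    the protocol and are exposed here.
    """

    depth_bush_threshold_m: float = 0.3
    hist_bin_m: float = 0.01
    noise_factor_t: float = 5.0
    sor_k: int = 10
    sor_n: float = 1.0
    dbscan_eps_m: float = 0.10
    dbscan_min_points: int = 10
    raster_cell_m: float = 0.5
    plane_tol_m: float = 0.03
    plane_iters: int = 1000
    plane_seed: int = 0

    def __post_init__(self):
        for name in ("depth_bush_threshold_m", "hist_bin_m", "noise_factor_t",
                     "sor_k", "sor_n", "dbscan_eps_m", "dbscan_min_points",
                     "raster_cell_m", "plane_tol_m", "plane_iters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AlignmentResult:
    """Rigid transform that levels the ground and orients the rows.

    ``theta_x/y/z`` are rotation angles (radians); ``T_x/y/z`` the matrices
    applied to row vectors as ``points @ T_x @ T_y @ T_z``. ``z_shift`` is
    subtracted afterwards so the ground sits at z ≈ 0.
    """

    theta_x: float
    theta_y: float
    theta_z: float
    T_x: np.ndarray
    T_y: np.ndarray
    T_z: np.ndarray
    ground_normal: np.ndarray
    z_shift: float = 0.0

    @property
    def rotation(self) -> np.ndarray:
        return self.T_x @ self.T_y @ self.T_z

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation - np.array([0.0, 0.0, self.z_shift])


@dataclass
class DepthRaster:
    """Per-cell maximum height grid. Empty cells hold NaN."""

    depth: np.ndarray            # (n_rows_y, n_cols_x), NaN = empty
    cell_size_m: float
    origin: tuple                # (x, y) of the corner of cell (0, 0)


@dataclass
class RowDetection:
    """Hough-space row line: angle alpha (rad), distance rho (m), votes."""

    alpha: float
    rho: float
    accumulator: np.ndarray
    heading_rad: float = 0.0     # in-plane angle of the row vs. the x axis


@dataclass
class HeightHistogram:
    """Height histogram (bin width 0.01 m) with forward-difference gradients."""

    bin_lower_limits: np.ndarray
    counts: np.ndarray
    gradients: np.ndarray        # counts[i+1] - counts[i], length = bins - 1


def _rot_x(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[1, 0, 0], [0, c, s], [0, -s, c]], dtype=float)


def _rot_y(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, s, 0], [-s, c, 0], [0, 0, 1]], dtype=float)


def fit_ground_plane(cloud: PointCloud, tol_m: float = 0.03,
                     n_iters: int = 1000, seed: int = 0,
                     min_support: float = 0.20):
    """Robust ground-plane fit (MLESAC-style sample consensus).

    Random 3-point hypotheses are scored with a truncated quadratic loss at
    ``tol_m`` and the best plane refined by least squares on its inliers.
    Returns ``(unit_normal, inlier_mask)`` with the normal oriented upward
    (positive z component).
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to fit a plane")
    rng = np.random.default_rng(seed)
    best_cost, best_normal, best_d = np.inf, None, 0.0
    tol2 = tol_m * tol_m
    for _ in range(n_iters):
        idx = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = pts[idx]
        nvec = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(nvec)
        if norm < 1e-12:
            continue
        nvec = nvec / norm
        dist = (pts - p0) @ nvec
        cost = np.minimum(dist * dist, tol2).sum()
        if cost < best_cost:
            best_cost, best_normal, best_d = cost, nvec, float(p0 @ nvec)
    if best_normal is None:
        raise ValueError("plane fit failed: all samples degenerate")
    inliers = np.abs(pts @ best_normal - best_d) <= tol_m
    if inliers.sum() < min_support * n:
        raise ValueError(
            f"no dominant plane: best support {inliers.sum()}/{n} "
            f"below {min_support:.0%}"
        )
    # least-squares refinement on inliers
    sub = pts[inliers]
    centroid = sub.mean(axis=0)
    _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    inliers = np.abs((pts - centroid) @ normal) <= tol_m
    return normal, inliers


def rasterize_depth(cloud: PointCloud, cell_size_m: float = 0.5) -> DepthRaster:
    """Grid the x-y plane and keep each cell's maximum z (NaN when empty)."""
    pts = cloud.points
    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    ix = np.floor((pts[:, 0] - x0) / cell_size_m).astype(int)
    iy = np.floor((pts[:, 1] - y0) / cell_size_m).astype(int)
    shape = (iy.max() + 1, ix.max() + 1)
    depth = np.full(shape, -np.inf)
    np.maximum.at(depth, (iy, ix), pts[:, 2])
    depth[np.isinf(depth)] = np.nan
    return DepthRaster(depth, cell_size_m, (float(x0), float(y0)))


def detect_row_direction(raster: DepthRaster,
                         bush_threshold_m: float = 0.3) -> RowDetection:
    """Find the planting-row line by a Hough transform on bush cells.

    Cells with depth above ``bush_threshold_m`` are bush pixels (empty cells
    take no part). The (alpha, rho) accumulator peak — the line collecting
    the most collinear bush pixels — gives the row direction; 1° angular
    steps, rho in raster-cell steps.
    """
    bush = np.zeros(raster.depth.shape, dtype=bool)
    occupied = ~np.isnan(raster.depth)
    bush[occupied] = raster.depth[occupied] > bush_threshold_m
    if bush.sum() < 3:
        raise ValueError(
            f"only {int(bush.sum())} bush cells above "
            f"{bush_threshold_m} m; cannot detect rows"
        )
    thetas = np.deg2rad(np.arange(-90.0, 90.0, 1.0))
    acc, angles, dists = hough_line(bush, theta=thetas)
    _, peak_angles, peak_dists = hough_line_peaks(acc, angles, dists,
                                                  num_peaks=1)
    theta = float(peak_angles[0])
    # hough_line images are indexed (row=y, col=x); theta is the normal angle
    alpha = theta % math.pi
    rho = float(peak_dists[0]) * raster.cell_size_m
    # direction along the line = normal angle + 90 degrees
    heading = theta + math.pi / 2.0
    # wrap to (-pi/2, pi/2]: an undirected row; +x orientation by convention
    while heading > math.pi / 2:
        heading -= math.pi
    while heading <= -math.pi / 2:
        heading += math.pi
    return RowDetection(alpha=alpha, rho=rho, accumulator=acc,
                        heading_rad=heading)


def _row_split_correction(xy: np.ndarray, heading_rad: float):
    """Rotate bush points by -heading, split into rows by across gaps and
    return (heading correction, supporting point count) from the per-row
    principal axes; (None, 0) when no elongated row is found."""
    c, s = math.cos(-heading_rad), math.sin(-heading_rad)
    rot = np.array([[c, -s], [s, c]])
    uv = xy @ rot.T
    v = uv[:, 1]
    # occupancy histogram across rows; sparse outlier bins don't count
    bin_m = 0.25
    edges = np.arange(v.min(), v.max() + 2 * bin_m, bin_m)
    counts, _ = np.histogram(v, bins=edges)
    occ = counts >= max(10, int(0.02 * counts.max()))
    corrections, weights = [], []
    i = 0
    while i < len(occ):
        if not occ[i]:
            i += 1
            continue
        j = i
        while j < len(occ) and occ[j]:
            j += 1
        row = uv[(v >= edges[i]) & (v < edges[j])]
        i = j
        if len(row) < 50:
            continue
        lo_u, hi_u = np.quantile(row[:, 0], (0.02, 0.98))
        lo_v, hi_v = np.quantile(row[:, 1], (0.02, 0.98))
        if hi_u - lo_u < 2.0 * (hi_v - lo_v):
            continue   # not elongated enough to define a direction
        centered = row - row.mean(axis=0)
        _, evecs = np.linalg.eigh(centered.T @ centered)
        d = evecs[:, -1]
        ang = math.atan2(d[1], d[0])
        if ang > math.pi / 2:
            ang -= math.pi
        elif ang <= -math.pi / 2:
            ang += math.pi
        corrections.append(ang)
        weights.append(len(row))
    if not corrections:
        return None, 0
    return float(np.average(corrections, weights=weights)), int(sum(weights))


def _refine_heading(xy: np.ndarray, coarse_rad: float) -> float:
    """Refine a coarse row heading from the bush points themselves.

    Bush points are rotated so rows run roughly along x, split into rows by
    gaps in the across-row coordinate, and each sufficiently elongated row
    contributes its principal-axis direction. The Hough accumulator on 0.5 m
    cells is only good to a few degrees for blob-like bushes; the per-row
    principal axis recovers the heading to well under a degree. When the
    coarse heading is too far off for the row split to work, candidate
    headings are swept and the best-supported one refined instead.
    """
    corr, support = _row_split_correction(xy, coarse_rad)
    if corr is None:
        best = (0, coarse_rad)
        for deg in range(-85, 90, 5):
            cand = math.radians(deg)
            c, s = _row_split_correction(xy, cand)
            if c is not None and s > best[0]:
                best = (s, cand + c)
        if best[0] == 0:
            return coarse_rad
        base = best[1]
        corr, _ = _row_split_correction(xy, base)
        return base + (corr or 0.0)
    return coarse_rad + corr


def align_cloud(cloud: PointCloud,
                config: PreprocessConfig | None = None
                ) -> tuple[PointCloud, AlignmentResult]:
    """Rigidly rotate a field scan: ground to the x-y plane, rows to +x.

    The composed transform is ``points @ T_x @ T_y @ T_z`` followed by a
    vertical shift placing the ground inliers at z ≈ 0. The rotation is
    rigid — pairwise distances are preserved exactly.
    """
    cfg = config or PreprocessConfig()
    normal, inliers = fit_ground_plane(cloud, cfg.plane_tol_m,
                                       cfg.plane_iters, cfg.plane_seed)
    # theta_x zeroes the normal's y component, theta_y then its x component
    theta_x = math.atan2(normal[1], normal[2])
    n1 = normal @ _rot_x(theta_x)
    theta_y = math.atan2(n1[0], n1[2])
    R_xy = _rot_x(theta_x) @ _rot_y(theta_y)

    leveled = cloud.points @ R_xy
    ground_z = np.median(leveled[inliers, 2])
    tmp = PointCloud(leveled - [0, 0, ground_z], source_id=cloud.source_id)
    raster = rasterize_depth(tmp, cfg.raster_cell_m)
    try:
        rows = detect_row_direction(raster, cfg.depth_bush_threshold_m)
        high = tmp.points[:, 2] > cfg.depth_bush_threshold_m
        heading = _refine_heading(tmp.points[high][:, :2], rows.heading_rad)
        # points @ T_z rotates by +theta_z; cancel the detected heading
        theta_z = -heading
    except ValueError:
        logger.warning("row detection failed; keeping current x orientation")
        theta_z = 0.0
    result = AlignmentResult(
        theta_x=theta_x, theta_y=theta_y, theta_z=theta_z,
        T_x=_rot_x(theta_x), T_y=_rot_y(theta_y), T_z=_rot_z(theta_z),
        ground_normal=normal,
    )
    rotated = cloud.points @ result.rotation
    result.z_shift = float(np.median(rotated[inliers, 2]))
    aligned = PointCloud(rotated - [0, 0, result.z_shift],
                         source_id=cloud.source_id,
                         attributes=dict(cloud.attributes))
    return aligned, result


def segment_bushes(cloud: PointCloud,
                   boxes: list[BoundingBox]) -> list[PointCloud]:
    """Crop one raw bush cloud per bounding box; empty boxes are skipped."""
    out = []
    for i, box in enumerate(boxes):
        try:
            sub = crop_box(cloud, box)
        except ValueError:
            logger.warning("bush box %d contains no points; skipped", i)
            continue
        sub.source_id = f"{cloud.source_id}#bush{i}"
        out.append(sub)
    return out


def height_histogram(cloud: PointCloud,
                     bin_m: float = 0.01) -> HeightHistogram:
    """Histogram of point heights with forward-difference bin gradients."""
    z = cloud.points[:, 2]
    lo = np.floor(z.min() / bin_m) * bin_m
    n_bins = int(np.ceil((z.max() - lo) / bin_m)) + 1
    edges = lo + bin_m * np.arange(n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    return HeightHistogram(
        bin_lower_limits=edges[:-1],
        counts=counts.astype(int),
        gradients=np.diff(counts.astype(int)),
    )


def ground_threshold(hist: HeightHistogram, t: float = 5.0) -> float:
    """Adaptive ground-height threshold from the histogram gradients.

    Ground points pile up in a sharp peak near the bottom of a raw bush
    cloud; the steepest count drop marks the top of that peak. The threshold
    is the smallest bin lower-limit h that lies above the steepest-descent
    bin and whose gradient magnitude is small but nonzero:

        h_ground = min({h : 0 < |G(h)| < t} ∩ {h : h > argmin_h G(h)})
    """
    G = hist.gradients
    if len(G) == 0:
        raise ValueError("histogram has a single bin; no gradients")
    h = hist.bin_lower_limits[:-1]   # G(h) pairs with the lower bin's limit
    h_steepest = h[int(np.argmin(G))]
    ok = (np.abs(G) > 0) & (np.abs(G) < t) & (h > h_steepest)
    if not ok.any():
        raise ValueError(
            f"no bin satisfies the ground-threshold rule (t={t}); "
            "try a larger noise factor t"
        )
    return float(h[ok].min())


def remove_ground(bush_cloud: PointCloud, h_ground: float) -> PointCloud:
    """Drop every point below ``h_ground``; the rest is the bush."""
    keep = bush_cloud.points[:, 2] >= h_ground
    if not keep.any():
        raise ValueError(f"h_ground={h_ground} removes every point")
    return bush_cloud.select(keep)


def sor_filter(cloud: PointCloud, k: int = 10, n: float = 1.0) -> PointCloud:
    """Statistical outlier removal.

    For each point, D(p, k) is the mean Euclidean distance to its k nearest
    neighbours. A point is noise when its D exceeds the cloud-wide mean of D
    by more than n standard deviations: D(p, k) > μ_D + n·δ_D.
    """
    pts = cloud.points
    if len(pts) <= k:
        raise ValueError(f"need more than k={k} points, got {len(pts)}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    dists, _ = nn.kneighbors(pts)
    D = dists[:, 1:].mean(axis=1)     # exclude the point itself
    keep = D <= D.mean() + n * D.std()
    return cloud.select(keep)


def largest_cluster(cloud: PointCloud, eps_m: float = 0.10,
                    min_points: int = 10) -> PointCloud:
    """Keep the largest density-based cluster (DBSCAN); noise is discarded.

    Size ties are broken deterministically in favour of the cluster
    containing the lowest point index.
    """
    labels = DBSCAN(eps=eps_m, min_samples=min_points).fit_predict(cloud.points)
    valid = labels >= 0
    if not valid.any():
        raise ValueError(
            f"DBSCAN found no cluster (eps={eps_m} m); try a larger eps"
        )
    ids, sizes = np.unique(labels[valid], return_counts=True)
    best_size = sizes.max()
    tied = ids[sizes == best_size]
    if len(tied) == 1:
        winner = tied[0]
    else:
        first_index = {c: int(np.argmax(labels == c)) for c in tied}
        winner = min(tied, key=lambda c: first_index[c])
    return cloud.select(labels == winner)


def clean_bush(raw_bush: PointCloud,
               config: PreprocessConfig | None = None) -> PointCloud:
    """Full per-bush cleaning: ground removal, SOR, largest cluster."""
    cfg = config or PreprocessConfig()
    hist = height_histogram(raw_bush, cfg.hist_bin_m)
    try:
        h_ground = ground_threshold(hist, cfg.noise_factor_t)
        bush = remove_ground(raw_bush, h_ground)
    except ValueError as exc:
        logger.warning("ground removal skipped (%s)", exc)
        bush = raw_bush
    if len(bush) > cfg.sor_k:
        bush = sor_filter(bush, cfg.sor_k, cfg.sor_n)
    bush = largest_cluster(bush, cfg.dbscan_eps_m, cfg.dbscan_min_points)
    logger.info("clean_bush %s: %d -> %d points", raw_bush.source_id,
                len(raw_bush), len(bush))
    return bush
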