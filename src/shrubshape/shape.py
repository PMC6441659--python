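"""Across-row bush silhouette analysis.

A clean bush cloud is projected onto the y-z plane and rasterized to a
binary mask at 0.01 m/pixel (image convention: origin at the top-left,
rows grow downward). Eleven landmark points and five construction lines
are detected on the mask, splitting the silhouette into crown (stem
region) and canopy. A one-parameter family of closed curves — the path
curve, λ = 1 a circle, λ < 1 vase-shaped, λ > 1 conical — is fitted to
the canopy contour by multi-start gradient descent on a nearest-contour
distance energy. Landmarks and fit yield five shape indices:

  NBR  non-canopy-to-bush height ratio (stem fraction of bush height)
  VR   h_upper / h_lower: position of the widest canopy row
  AR   fitted curve height / width
  CN   curvedness: fitted-curve area outside the two canopy triangles
  IRR  irregularity: canopy silhouette area outside the fitted curve
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_closing, binary_fill_holes, \
    distance_transform_edt
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon
from skimage.morphology import skeletonize
from skimage.measure import label as cc_label

from . import pathcurve
from .io import PointCloud

__all__ = [
    "BushMask",
    "LandmarkSet",
    "PathCurveConfig",
    "PathCurveFit",
    "ShapeIndices",
    "project_mask",
    "detect_landmarks",
    "path_curve_points",
    "curve_energy",
    "fit_path_curve",
    "shape_indices",
    "analyze_shape",
]


@dataclass
class BushMask:
    """Binary across-row silhouette raster.

    ``mask[row, col]``: row 0 is the top of the bush (image convention,
    y down); columns map the across-row axis. ``grid_m`` meters per pixel.
    """

    mask: np.ndarray
    grid_m: float = 0.01
    origin_yz: tuple = (0.0, 0.0)   # (y, z) of pixel (row=0, col=0)

    def __post_init__(self):
        if not self.mask.any():
            raise ValueError("bush mask is empty")


@dataclass
class LandmarkSet:
    """Landmark pixels (row, col) and construction lines of a bush mask.

    P1 top center; P2/P3 widest-row ends; P4/P5 extreme left/right; P6/P7
    crown-canopy separation points (optional); P8/P9/P10 bottom row ends and
    center; P11 canopy-bottom center (falls back to P9 when P6 and P7 are
    both absent). Lines are pixel-coordinate two-point segments.
    """

    P: dict = field(default_factory=dict)   # name -> (row, col) or None
    lines: dict = field(default_factory=dict)
    separation_row: int = 0
    widest_row: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def has_stem(self) -> bool:
        return self.P.get("P6") is not None or self.P.get("P7") is not None


@dataclass
class PathCurveConfig:
    """Fitting controls for the path-curve optimizer.

    The multi-start grid runs w and h from half to the full canopy bounding
    box in 5-pixel increments; each start is refined by finite-difference
    gradient descent on the contour-distance energy with patience-5 /
    500-iteration stopping.
    """

    init_step_px: int = 5
    lambda_init: float = 1.0
    max_iter: int = 500
    patience: int = 5
    n_curve_samples: int = 1500
    lr: float = 4.0
    min_change: float = 1e-6
    fd_steps: tuple = (1.0, 1.0, 0.01, 1.0, 1.0)  # w, h, lambda, off_m, off_n


@dataclass
class PathCurveFit:
    """Fitted path curve in mask pixel coordinates."""

    w_ptc: float            # width, px
    h_ptc: float            # height, px
    lam: float              # shape factor λ
    offset_m: float         # column of the symmetry axis
    offset_n: float         # row of the canopy top tip
    energy: float
    curve_pixels: np.ndarray = None   # (K, 2) rows/cols, deduplicated
    n_starts: int = 0

    def summary(self) -> str:
        shape = ("circle" if abs(self.lam - 1) < 0.05
                 else "vase" if self.lam < 1 else "conical")
        return (
            f"PathCurveFit: lambda={self.lam:.3f} ({shape}), "
            f"w={self.w_ptc:.1f} px, h={self.h_ptc:.1f} px, "
            f"energy={self.energy:.4f} ({self.n_starts} starts)"
        )


@dataclass
class ShapeIndices:
    NBR: float
    VR: float
    AR: float
    CN: float
    IRR: float
    h_n: float = 0.0
    h_upper: float = 0.0
    h_lower: float = 0.0
    h_bush: float = 0.0
    area_upper: int = 0
    area_lower: int = 0
    area_fitted: int = 0
    area_canopy: int = 0

    def as_row(self) -> dict:
        return {"NBR": self.NBR, "VR": self.VR, "AR": self.AR,
                "CN": self.CN, "IRR": self.IRR}


def project_mask(cloud: PointCloud, grid_m: float = 0.01) -> BushMask:
    """Project a clean bush cloud to its across-row silhouette mask.

    Points are dropped onto the y-z plane and rasterized at ``grid_m``.
    Pixel intensity is the point depth along x (distance to the bush's
    near face); any hit makes a foreground pixel. Morphological closing
    fills small holes, speckles are removed, and the largest connected
    component is kept.
    """
    pts = cloud.points
    y, z = pts[:, 1], pts[:, 2]
    y0, z1 = y.min(), z.max()
    cols = np.floor((y - y0) / grid_m).astype(int)
    rows = np.floor((z1 - z) / grid_m).astype(int)
    n_rows, n_cols = rows.max() + 1, cols.max() + 1
    depth = pts[:, 0] - pts[:, 0].min()
    gray = np.zeros((n_rows, n_cols))
    np.maximum.at(gray, (rows, cols), depth + 1e-9)
    raw = np.pad(gray > 0.0, 2)   # pad so closing cannot erode the border
    closed = binary_closing(raw, structure=np.ones((3, 3)))[2:-2, 2:-2]
    cleaned = binary_fill_holes(closed)
    labels = cc_label(cleaned, connectivity=2)
    if labels.max() > 1:
        sizes = np.bincount(labels.ravel())[1:]
        cleaned = labels == (1 + int(np.argmax(sizes)))
    return BushMask(cleaned, grid_m, origin_yz=(float(y0), float(z1)))


def _row_extent(mask_row: np.ndarray):
    cols = np.flatnonzero(mask_row)
    return (int(cols[0]), int(cols[-1])) if len(cols) else None


def _line_through(p: tuple, q: tuple):
    """Return f(col) -> row for the line through two (row, col) pixels; None
    for vertical lines."""
    (r1, c1), (r2, c2) = p, q
    if c1 == c2:
        return None
    slope = (r2 - r1) / (c2 - c1)
    return lambda c: r1 + slope * (np.asarray(c, dtype=float) - c1)


def _point_line_distance(points: np.ndarray, p: tuple, q: tuple) -> np.ndarray:
    """Distance from (row, col) points to the infinite line through p, q."""
    p = np.array(p, dtype=float)
    d = np.array(q, dtype=float) - p
    norm = np.linalg.norm(d)
    rel = points - p
    return np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]) / norm


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    padded = np.pad(skel, 1).astype(int)
    return sum(
        np.roll(np.roll(padded, dr, 0), dc, 1)
        for dr in (-1, 0, 1) for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    )[1:-1, 1:-1]


def _branch_length(skel: np.ndarray, counts: np.ndarray,
                   end: tuple, limit: int) -> int:
    """Pixels walked from an endpoint until a skeleton branch point (or
    ``limit``). Short branches are pixelation spurs, not real structure."""
    r, c = end
    prev = None
    for step in range(limit):
        if counts[r, c] >= 3:
            return step
        nxt = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] \
                        and skel[rr, cc] and (rr, cc) != prev:
                    nxt = (rr, cc)
                    break
            if nxt:
                break
        if nxt is None:
            return step
        prev, (r, c) = (r, c), nxt
    return limit


def _skeleton_endpoints(mask: np.ndarray,
                        min_branch_px: int = 5) -> np.ndarray:
    """Endpoints of the mask skeleton (pixels with one 8-connected skeleton
    neighbour), excluding tips of branches shorter than ``min_branch_px`` —
    those are rasterization spurs, not stem/crotch structure."""
    skel = skeletonize(mask)
    counts = _neighbour_counts(skel)
    ends = np.argwhere(skel & (counts == 1))
    keep = [
        e for e in ends
        if _branch_length(skel, counts, tuple(e), min_branch_px)
        >= min_branch_px
    ]
    return np.array(keep, dtype=int).reshape(-1, 2)


def _pick_p6(endpoints: np.ndarray, L1: tuple, quadrant: np.ndarray,
             diagnostics: dict, side: str):
    """Separation-point rule on one side: among lower-quadrant skeleton
    endpoints above L1, candidates lie within one MAD of the maximal
    distance to L1 (and above the median + MAD floor); the candidate
    closest to the bush bottom (largest row) wins."""
    pts = endpoints[quadrant]
    if len(pts) == 0:
        return None
    # Med/MAD floor over the whole quadrant's endpoint population; the
    # above-L1 requirement applies to candidates only
    D = _point_line_distance(pts.astype(float), *L1)
    med = np.median(D)
    mad = np.median(np.abs(D - med))
    diagnostics[f"D_{side}"] = D
    diagnostics[f"Med_{side}"] = float(med)
    diagnostics[f"MAD_{side}"] = float(mad)
    f_l1 = _line_through(*L1)
    if f_l1 is None:
        above = np.zeros(len(pts), dtype=bool)  # vertical L1: none "above"
    else:
        above = pts[:, 0] < f_l1(pts[:, 1])
    floor = med + mad
    cand = (D >= D.max() - mad) & (D > floor) & above
    if not cand.any():
        return None
    chosen = pts[cand]
    return tuple(int(v) for v in chosen[np.argmax(chosen[:, 0])])


def detect_landmarks(bush_mask: BushMask) -> LandmarkSet:
    """Detect the 11 landmark points and 5 construction lines of a mask."""
    mask = bush_mask.mask
    fg_rows = np.flatnonzero(mask.any(axis=1))
    if len(fg_rows) < 3:
        raise ValueError("mask shorter than 3 rows; cannot place landmarks")
    top, bottom = int(fg_rows[0]), int(fg_rows[-1])

    lm = LandmarkSet()
    P = lm.P

    lo, hi = _row_extent(mask[top])
    P["P1"] = (top, (lo + hi) // 2)

    widths = np.array([
        (e[1] - e[0]) if (e := _row_extent(mask[r])) else -1
        for r in range(mask.shape[0])
    ])
    widest = int(np.argmax(widths))        # argmax takes the uppermost tie
    lo, hi = _row_extent(mask[widest])
    P["P2"], P["P3"] = (widest, lo), (widest, hi)
    lm.widest_row = widest

    fg_cols = np.flatnonzero(mask.any(axis=0))
    left_col, right_col = int(fg_cols[0]), int(fg_cols[-1])
    P["P4"] = (int(np.argwhere(mask[:, left_col]).max()), left_col)
    P["P5"] = (int(np.argwhere(mask[:, right_col]).max()), right_col)

    lo, hi = _row_extent(mask[bottom])
    P["P8"], P["P10"] = (bottom, lo), (bottom, hi)
    P["P9"] = (bottom, (lo + hi) // 2)

    # lower of {P2, P4} anchors the left border/boundary lines (image rows
    # grow downward, so "closer to the bush bottom" = larger row)
    left_anchor = max(P["P2"], P["P4"], key=lambda p: p[0])
    right_anchor = max(P["P3"], P["P5"], key=lambda p: p[0])
    lm.lines["LL"] = ((left_anchor[0], 0), (left_anchor[0], mask.shape[1] - 1))
    lm.lines["LR"] = ((right_anchor[0], 0), (right_anchor[0], mask.shape[1] - 1))
    lm.lines["L1"] = (P["P8"], left_anchor)
    lm.lines["L2"] = (P["P10"], right_anchor)
    lm.lines["LM"] = ((0, P["P9"][1]), (mask.shape[0] - 1, P["P9"][1]))

    endpoints = _skeleton_endpoints(mask)
    mid_col = P["P9"][1]
    if len(endpoints):
        lower_left = (endpoints[:, 1] < mid_col) & \
                     (endpoints[:, 0] > left_anchor[0])
        lower_right = (endpoints[:, 1] > mid_col) & \
                      (endpoints[:, 0] > right_anchor[0])
        P["P6"] = _pick_p6(endpoints, lm.lines["L1"], lower_left,
                           lm.diagnostics, "ll")
        P["P7"] = _pick_p6(endpoints, lm.lines["L2"], lower_right,
                           lm.diagnostics, "lr")
    else:
        P["P6"] = P["P7"] = None

    present = [p for p in (P["P6"], P["P7"]) if p is not None]
    if present:
        sep_row = max(p[0] for p in present)   # the one closer to the bottom
        ext = _row_extent(mask[sep_row])
        if ext is None:
            sep_row, ext = bottom, _row_extent(mask[bottom])
        P["P11"] = (sep_row, (ext[0] + ext[1]) // 2)
    else:
        sep_row = bottom
        P["P11"] = P["P9"]
    lm.separation_row = int(sep_row)
    return lm


def path_curve_points(w_ptc: float, h_ptc: float, lam: float,
                      offset_m: float, offset_n: float,
                      cfg: PathCurveConfig | None = None) -> np.ndarray:
    """Render a path curve as a deduplicated (row, col) pixel set.

    ``offset_m`` is the column of the symmetry axis, ``offset_n`` the row of
    the curve's top tip; rows grow downward, matching the mask convention.
    """
    cfg = cfg or PathCurveConfig()
    if h_ptc <= 0:
        raise ValueError("h_ptc must be positive (t_max undefined otherwise)")
    # oversample so adjacent samples land on adjacent pixels (gap-free loop)
    n = max(cfg.n_curve_samples, int(12 * (abs(w_ptc) + abs(h_ptc))))
    x_half, y = pathcurve.curve_xy(w_ptc, h_ptc, lam, n)
    cols = np.concatenate([offset_m - x_half, offset_m + x_half])
    rows = np.concatenate([offset_n + y, offset_n + y])
    px = np.round(np.column_stack([rows, cols])).astype(int)
    return np.unique(px, axis=0)


def curve_energy(curve_pixels: np.ndarray,
                 contour_pixels: np.ndarray) -> float:
    """Path-curve fitting energy: sqrt(sum of nearest-contour distances) / n.

    Each curve pixel contributes its Euclidean distance to the nearest
    canopy-contour pixel; the square root of the summed distances is
    divided by the number of curve pixels.
    """
    if len(contour_pixels) == 0:
        raise ValueError("empty canopy contour")
    if len(curve_pixels) == 0:
        raise ValueError("empty curve pixel set")
    tree = cKDTree(np.asarray(contour_pixels, dtype=float))
    d, _ = tree.query(np.asarray(curve_pixels, dtype=float))
    return float(np.sqrt(d.sum()) / len(curve_pixels))


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """Outer boundary pixels of a binary mask (foreground pixels with a
    4-connected background neighbour)."""
    interior = np.ones_like(mask)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.zeros_like(mask)
        src = mask[max(dr, 0) or None: mask.shape[0] + min(dr, 0),
                   max(dc, 0) or None: mask.shape[1] + min(dc, 0)]
        shifted[max(-dr, 0) or None: mask.shape[0] + min(-dr, 0),
                max(-dc, 0) or None: mask.shape[1] + min(-dc, 0)] = src
        interior &= shifted
    return np.argwhere(mask & ~interior)


def _render_batch(params: np.ndarray, t: np.ndarray):
    """Render B path curves at once; returns pixel array and segment ids.

    ``params`` is (B, 5): w, h, lam, offset_m, offset_n.
    """
    w = params[:, 0:1]
    h = params[:, 1:2]
    lam = params[:, 2:3]
    off_m = params[:, 3:4]
    off_n = params[:, 4:5]
    tm = np.log(2.0 * lam / h) / (lam + 1.0)
    denom_tm = np.exp(-lam * tm) + 0.5 * h * np.exp(tm)
    w_base = 0.5 * w * denom_tm
    a = 1.0 / (np.exp(-lam * t[None, :]) + 0.5 * h * np.exp(t[None, :]))
    x_half = w_base * a
    y = a * np.exp(t[None, :]) * h * h / 2.0
    rows = np.rint(np.concatenate([off_n + y, off_n + y], axis=1)).astype(np.int64)
    cols = np.rint(np.concatenate([off_m - x_half, off_m + x_half],
                                  axis=1)).astype(np.int64)
    return rows, cols


def _batch_energies(params: np.ndarray, t: np.ndarray, dist_lookup) -> np.ndarray:
    """Energy of each parameter row, deduplicating pixels per curve."""
    rows, cols = _render_batch(params, t)
    B, L = rows.shape
    # encode (curve, row, col) into one integer for a single unique pass
    r = rows - rows.min() + 1
    c = cols - cols.min() + 1
    span_c = c.max() + 2
    span_r = r.max() + 2
    curve_id = np.repeat(np.arange(B, dtype=np.int64)[:, None], L, axis=1)
    code = (curve_id * span_r + r) * span_c + c
    uniq = np.unique(code)
    uc = uniq % span_c + cols.min() - 1
    rem = uniq // span_c
    ur = rem % span_r + rows.min() - 1
    ub = rem // span_r
    d = dist_lookup(ur, uc)
    sums = np.bincount(ub, weights=d, minlength=B)
    counts = np.bincount(ub, minlength=B)
    return np.sqrt(sums) / np.maximum(counts, 1)


def fit_path_curve(bush_mask: BushMask, landmarks: LandmarkSet | None = None,
                   cfg: PathCurveConfig | None = None) -> PathCurveFit:
    """Fit the path curve to the canopy contour of a bush mask.

    The canopy is the mask above the crown-canopy separation row. Every
    (w, h) pair on the initialization grid — half to full canopy bounding
    box, 5-pixel steps — seeds a finite-difference gradient descent on the
    contour-distance energy (λ starts at 1, offsets at the canopy top
    center). Descent stops when the energy decrease stays below
    ``min_change`` for ``patience`` iterations or at ``max_iter``. The
    lowest-energy curve across all starts wins. Deterministic.
    """
    cfg = cfg or PathCurveConfig()
    if landmarks is None:
        landmarks = detect_landmarks(bush_mask)
    canopy = bush_mask.mask[: landmarks.separation_row + 1]
    if not canopy.any():
        raise ValueError("canopy sub-mask is empty above the separation row")
    contour = mask_contour(canopy)

    # nearest-contour distances: precomputed exact distance transform on a
    # padded canvas (O(1) per pixel), KD-tree fallback off-canvas
    pad = 80
    canvas = np.zeros((canopy.shape[0] + 2 * pad,
                       bush_mask.mask.shape[1] + 2 * pad), dtype=bool)
    canvas[contour[:, 0] + pad, contour[:, 1] + pad] = True
    dist_img = distance_transform_edt(~canvas)
    tree = cKDTree(contour.astype(float))

    def dist_lookup(r, c):
        rr = r + pad
        cc = c + pad
        inside = (rr >= 0) & (rr < canvas.shape[0]) & \
                 (cc >= 0) & (cc < canvas.shape[1])
        d = np.empty(len(rr))
        d[inside] = dist_img[rr[inside], cc[inside]]
        if not inside.all():
            q, _ = tree.query(np.column_stack([r[~inside], c[~inside]])
                              .astype(float))
            d[~inside] = q
        return d

    rows = np.flatnonzero(canopy.any(axis=1))
    cols = np.flatnonzero(canopy.any(axis=0))
    h_can = rows[-1] - rows[0] + 1
    w_can = cols[-1] - cols[0] + 1
    off_m0 = 0.5 * (cols[0] + cols[-1])
    off_n0 = float(rows[0])

    w_inits = np.arange(np.ceil(w_can / 2.0), w_can + 1, cfg.init_step_px)
    h_inits = np.arange(np.ceil(h_can / 2.0), h_can + 1, cfg.init_step_px)
    t = np.linspace(*pathcurve.T_DOMAIN, cfg.n_curve_samples)
    fd = np.asarray(cfg.fd_steps)
    lower = np.array([3.0, 3.0, 0.02, -1e9, -1e9])

    best = None
    n_starts = 0
    for w0 in w_inits:
        for h0 in h_inits:
            n_starts += 1
            theta = np.array([w0, h0, cfg.lambda_init, off_m0, off_n0],
                             dtype=float)
            lr = cfg.lr
            energy = _batch_energies(theta[None, :], t, dist_lookup)[0]
            stall = 0
            for _ in range(cfg.max_iter):
                pert = np.repeat(theta[None, :], 10, axis=0)
                for j in range(5):
                    pert[2 * j, j] += fd[j]
                    pert[2 * j + 1, j] -= fd[j]
                np.maximum(pert, lower, out=pert)
                e = _batch_energies(pert, t, dist_lookup)
                grad = (e[0::2] - e[1::2]) / (2.0 * fd)
                gnorm = np.linalg.norm(grad)
                if gnorm < 1e-12:
                    break
                cand = np.maximum(theta - lr * grad / gnorm * fd, lower)
                e_cand = _batch_energies(cand[None, :], t, dist_lookup)[0]
                if e_cand < energy - cfg.min_change:
                    theta, energy, stall = cand, e_cand, 0
                else:
                    lr *= 0.5
                    stall += 1
                    if stall >= cfg.patience:
                        break
            if best is None or energy < best[0]:
                best = (energy, theta.copy())

    energy, theta = best
    pixels = path_curve_points(*theta, cfg)
    return PathCurveFit(
        w_ptc=float(theta[0]), h_ptc=float(theta[1]), lam=float(theta[2]),
        offset_m=float(theta[3]), offset_n=float(theta[4]),
        energy=float(energy), curve_pixels=pixels, n_starts=n_starts,
    )


def _filled_curve_area(fit: PathCurveFit, shape: tuple) -> np.ndarray:
    """Boolean canvas of pixels inside the fitted closed curve."""
    px = fit.curve_pixels
    r0, c0 = px.min(axis=0)
    canvas = np.zeros((px[:, 0].max() - r0 + 3, px[:, 1].max() - c0 + 3),
                      dtype=bool)
    canvas[px[:, 0] - r0 + 1, px[:, 1] - c0 + 1] = True
    filled = binary_fill_holes(canvas)
    out = np.zeros(shape, dtype=bool)
    rr, cc = np.nonzero(filled)
    rr = rr + r0 - 1
    cc = cc + c0 - 1
    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    out[rr[ok], cc[ok]] = True
    return out


def shape_indices(landmarks: LandmarkSet, fit: PathCurveFit,
                  bush_mask: BushMask) -> ShapeIndices:
    """Compute the five shape indices from landmarks, fit and mask.

    Heights are in pixels (ratios are unitless): h_upper from P1 down to
    the widest row, h_lower from the widest row to the canopy bottom P11,
    h_n from P11 to the bush bottom P9. Areas are pixel counts; the canopy
    triangles are (P1, P2, P3) above the widest row and (P11, P2, P3)
    below it. IRR uses the set difference canopy \\ fitted-curve region,
    so it lies in [0, 1] by construction.
    """
    P = landmarks.P
    h_upper = landmarks.widest_row - P["P1"][0]
    h_lower = P["P11"][0] - landmarks.widest_row
    h_n = P["P9"][0] - P["P11"][0]
    h_bush = h_n + h_lower + h_upper
    if h_lower <= 0:
        raise ValueError("h_lower = 0: widest row at the canopy bottom, "
                         "VR undefined")

    shape = bush_mask.mask.shape
    fitted_region = _filled_curve_area(fit, shape)
    area_fitted = int(fitted_region.sum())

    def tri_area(p, q, r):
        rr, cc = draw_polygon([p[0], q[0], r[0]], [p[1], q[1], r[1]], shape)
        return len(rr)

    area_upper = tri_area(P["P1"], P["P2"], P["P3"])
    area_lower = tri_area(P["P11"], P["P2"], P["P3"])

    canopy_region = bush_mask.mask.copy()
    canopy_region[landmarks.separation_row + 1:] = False
    area_canopy = int(canopy_region.sum())
    if area_fitted == 0 or area_canopy == 0:
        raise ValueError("zero fitted-curve or canopy area")

    nbr = h_n / h_bush
    vr = h_upper / h_lower
    ar = fit.h_ptc / fit.w_ptc
    cn = (area_fitted - area_upper - area_lower) / area_fitted
    irr = int((canopy_region & ~fitted_region).sum()) / area_canopy
    return ShapeIndices(
        NBR=float(nbr), VR=float(vr), AR=float(ar), CN=float(cn),
        IRR=float(min(max(irr, 0.0), 1.0)),
        h_n=float(h_n), h_upper=float(h_upper), h_lower=float(h_lower),
        h_bush=float(h_bush), area_upper=area_upper, area_lower=area_lower,
        area_fitted=area_fitted, area_canopy=area_canopy,
    )


def analyze_shape(cloud: PointCloud, grid_m: float = 0.01,
                  cfg: PathCurveConfig | None = None):
    """Full shape analysis of one clean bush cloud.

    Returns ``(mask, landmarks, fit, indices)``.
    """
    mask = project_mask(cloud, grid_m)
    landmarks = detect_landmarks(mask)
    fit = fit_path_curve(mask, landmarks, cfg)
    indices = shape_indices(landmarks, fit, mask)
    return mask, landmarks, fit, indices
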