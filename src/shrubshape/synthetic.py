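"""Synthetic bush and field point-cloud generation with known ground truth.

Every downstream stage of the pipeline (alignment, ground removal, outlier
filtering, trait and shape extraction) is exercised against clouds generated
here, for which the true height, widths, crown diameter, shape factor λ and
canopy volume are known analytically.

A synthetic bush consists of
  * a *crown*: points on a vertical cylinder of the stated diameter and
    height — the stem region a mechanical harvester's catch plates close
    around, and
  * a *canopy*: points on the surface of revolution of a path curve with the
    stated width, height and λ, sitting on top of the crown.

Sensor imperfections are emulated with isotropic Gaussian jitter and
uniformly scattered outlier points. Fields place bushes in rows on a tilted,
rough ground plane, optionally with weed clusters between the rows, and label
every point (ground / bush index / weed) so segmentation accuracy can be
scored exactly.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import pathcurve
from .io import BoundingBox, PointCloud

__all__ = [
    "BushSpec",
    "FieldSpec",
    "GroundTruth",
    "generate_bush",
    "generate_field",
    "cylinder_layer_volume",
]


@dataclass
class BushSpec:
    """Parameters of one synthetic bush (lengths in meters)."""

    canopy_width_m: float = 1.0
    canopy_height_m: float = 1.0
    lambda_true: float = 1.0
    crown_diameter_m: float = 0.20
    crown_height_m: float = 0.30
    n_stems: int = 1
    stem_radius_m: float = 0.02
    n_twigs: int = 0
    lean_angle_deg: float = 0.0
    point_density: float = 3000.0  # points per m^2 of surface
    noise_sigma_m: float = 0.0
    n_outliers: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("canopy_width_m", "canopy_height_m", "crown_diameter_m",
                     "crown_height_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lambda_true <= 0:
            raise ValueError("lambda_true must be > 0")
        if not (0.02 <= self.lambda_true <= 50):
            raise ValueError(
                f"lambda_true={self.lambda_true} is degenerate: the path "
                "curve collapses outside [0.02, 50]"
            )
        if self.noise_sigma_m < 0:
            raise ValueError("noise_sigma_m must be >= 0")


@dataclass
class FieldSpec:
    """Parameters of a multi-row synthetic field."""

    bush_specs: list = field(default_factory=list)  # list of rows, each a list of BushSpec
    row_spacing_m: float = 3.0
    plant_spacing_m: float = 1.5
    ground_slope_deg: float = 0.0
    ground_roughness_m: float = 0.0
    row_heading_deg: float = 0.0
    n_weed_clusters: int = 0
    ground_density: float = 1000.0  # points per m^2 of ground
    seed: int = 0

    def __post_init__(self):
        if self.row_spacing_m <= 0 or self.plant_spacing_m <= 0:
            raise ValueError("spacings must be > 0")
        if not (0 <= self.ground_slope_deg < 45):
            raise ValueError("ground_slope_deg must be in [0, 45)")


@dataclass
class GroundTruth:
    """Analytic truth record for one generated bush."""

    bush_id: int
    height_m: float
    wir_m: float
    war_m: float
    crown_m: float
    lambda_true: float
    volume_m3: float
    box: BoundingBox
    spec: BushSpec = None

    def as_row(self) -> dict:
        return {
            "bush_id": self.bush_id,
            "height_m": self.height_m,
            "wir_m": self.wir_m,
            "war_m": self.war_m,
            "crown_m": self.crown_m,
            "lambda": self.lambda_true,
            "volume_m3": self.volume_m3,
        }


def _sample_canopy_surface(spec: BushSpec, rng) -> np.ndarray:
    """Sample points on the path-curve surface of revolution.

    Sampling is area-weighted along the profile (arc length x ring
    circumference) so surface density is approximately uniform, matching what
    a scanner sees (surface returns only, no interior points).
    """
    w, h, lam = spec.canopy_width_m, spec.canopy_height_m, spec.lambda_true
    x_half, y_img = pathcurve.curve_xy(w, h, lam, 4000)
    z_rel = h - y_img  # physical height above canopy base
    r = x_half
    ds = np.hypot(np.diff(r), np.diff(z_rel))
    ring = 2 * np.pi * 0.5 * (r[:-1] + r[1:])
    seg_area = ds * ring
    area = seg_area.sum()
    n = max(int(spec.point_density * area), 50)
    seg = rng.choice(len(seg_area), size=n, p=seg_area / area)
    frac = rng.uniform(size=n)
    rr = r[seg] + frac * (r[seg + 1] - r[seg])
    zz = z_rel[seg] + frac * (z_rel[seg + 1] - z_rel[seg])
    phi = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([rr * np.cos(phi), rr * np.sin(phi),
                            zz + spec.crown_height_m])


def _sample_crown_surface(spec: BushSpec, rng) -> np.ndarray:
    """Points on the crown (stem region) below the canopy, base at z = 0.

    ``n_stems = 1``: one cylinder of radius crown_diameter/2 — the simplest
    crown with an exactly known envelope at every height. ``n_stems > 1``:
    that many thin canes (radius ``stem_radius_m``) spreading outward from
    the base center so their envelope reaches ``crown_diameter_m`` at the
    canopy base; the silhouette gaps between spread canes are what makes the
    crown-canopy separation landmarks detectable, as on real bushes.
    """
    h = spec.crown_height_m
    if spec.n_stems <= 1:
        radius = spec.crown_diameter_m / 2.0
        area = 2 * np.pi * radius * h
        n = max(int(spec.point_density * area), 30)
        phi = rng.uniform(0, 2 * np.pi, size=n)
        z = rng.uniform(0, h, size=n)
        return np.column_stack([radius * np.cos(phi),
                                radius * np.sin(phi), z])
    r_s = spec.stem_radius_m
    ring = spec.crown_diameter_m / 2.0 - r_s
    # vertical canes on a ring, phased so that no cane sits under the canopy
    # center in the across-row projection — the canopy's bottom tip then
    # dangles visibly between canes, as on real open-crowned bushes
    angles = 2 * np.pi * np.arange(spec.n_stems) / spec.n_stems \
        + np.pi / (2 * spec.n_stems)
    per_stem = max(int(spec.point_density * 2 * np.pi * r_s * h), 60)
    parts = []
    for ang in angles:
        z = rng.uniform(0, h, size=per_stem)
        phi = rng.uniform(0, 2 * np.pi, size=per_stem)
        cx = np.cos(ang) * ring
        cy = np.sin(ang) * ring
        parts.append(np.column_stack([cx + r_s * np.cos(phi),
                                      cy + r_s * np.sin(phi), z]))
    return np.vstack(parts)


def _sample_twigs(spec: BushSpec, rng) -> np.ndarray:
    """Drooping laterals hanging just below the canopy underside.

    Real bushes carry short fruiting shoots that dangle 1–3 cm below the
    canopy base between the canes; their silhouette tips are exactly the
    skeleton endpoints the crown-canopy separation landmarks key on.
    """
    w, h = spec.canopy_width_m, spec.canopy_height_m
    x_half, y_img = pathcurve.curve_xy(w, h, spec.lambda_true, 2000)
    z_rel = h - y_img   # height above the canopy base
    lower = z_rel < 0.35 * h
    ring = max(spec.crown_diameter_m / 2.0 - spec.stem_radius_m, 0.01)
    parts = []
    for i in range(spec.n_twigs):
        if i % 2 == 0:
            # hanging fruiting lateral below the canopy underside
            r_base = rng.uniform(0.1, 0.6) * w / 2.0
            z0 = np.interp(r_base, x_half[lower], z_rel[lower])
            phi = rng.uniform(0, 2 * np.pi)
            base = np.array([r_base * np.cos(phi), r_base * np.sin(phi),
                             spec.crown_height_m + z0])
            drop = z0 + rng.uniform(0.005, 0.025)
            direction = np.array([rng.normal(scale=0.15),
                                  rng.normal(scale=0.15), -1.0])
        else:
            # outward lateral off one of the actual canes
            cane_angles = (2 * np.pi * np.arange(max(spec.n_stems, 1))
                           / max(spec.n_stems, 1)
                           + np.pi / (2 * max(spec.n_stems, 1)))
            phi = cane_angles[rng.integers(len(cane_angles))] \
                + rng.normal(scale=0.05)
            zc = rng.uniform(0.3, 0.9) * spec.crown_height_m
            base = np.array([ring * np.cos(phi), ring * np.sin(phi), zc])
            drop = rng.uniform(0.04, 0.10)
            direction = np.array([np.cos(phi) + rng.normal(scale=0.2),
                                  np.sin(phi) + rng.normal(scale=0.2),
                                  -rng.uniform(0.3, 1.0)])
        direction /= np.linalg.norm(direction)
        tt = np.linspace(0, drop, max(int(drop * 400), 10))
        twig = base + tt[:, None] * direction
        twig += rng.normal(scale=0.003, size=twig.shape)
        parts.append(twig)
    return np.vstack(parts) if parts else np.empty((0, 3))


def generate_bush(spec: BushSpec) -> tuple[PointCloud, GroundTruth]:
    """Generate one bush at the origin (crown base at z = 0).

    Deterministic for a fixed ``spec.seed``. Points carry an ``attributes``
    label array: 0 = canopy/crown surface, 2 = outlier.
    """
    rng = np.random.default_rng(spec.seed)
    canopy = _sample_canopy_surface(spec, rng)
    crown = _sample_crown_surface(spec, rng)
    twigs = _sample_twigs(spec, rng)
    pts = np.vstack([crown, canopy, twigs])

    if spec.lean_angle_deg:
        a = math.radians(spec.lean_angle_deg)
        rot = np.array([[1, 0, 0],
                        [0, math.cos(a), -math.sin(a)],
                        [0, math.sin(a), math.cos(a)]])
        pts = pts @ rot.T  # rigid lean about the base (x axis)

    if spec.noise_sigma_m > 0:
        pts = pts + rng.normal(scale=spec.noise_sigma_m, size=pts.shape)

    labels = np.zeros(len(pts), dtype=int)
    if spec.n_outliers:
        span = max(spec.canopy_width_m, spec.crown_height_m
                   + spec.canopy_height_m)
        out = rng.uniform(-span, span, size=(spec.n_outliers, 3))
        out[:, 2] = rng.uniform(0, spec.crown_height_m + spec.canopy_height_m,
                                size=spec.n_outliers)
        pts = np.vstack([pts, out])
        labels = np.concatenate([labels, np.full(spec.n_outliers, 2)])

    height = spec.crown_height_m + spec.canopy_height_m
    volume = (pathcurve.revolution_volume(spec.canopy_width_m,
                                          spec.canopy_height_m,
                                          spec.lambda_true)
              + np.pi * (spec.crown_diameter_m / 2) ** 2 * spec.crown_height_m)
    truth = GroundTruth(
        bush_id=0,
        height_m=height,
        wir_m=spec.canopy_width_m,
        war_m=spec.canopy_width_m,
        crown_m=spec.crown_diameter_m,
        lambda_true=spec.lambda_true,
        volume_m3=volume,
        # box bounds the bush itself, not the scattered outliers — it plays
        # the role of a manually drawn per-bush box
        box=BoundingBox(pts[labels == 0].min(axis=0),
                        pts[labels == 0].max(axis=0)),
        spec=spec,
    )
    cloud = PointCloud(pts, source_id=f"synthetic_bush(seed={spec.seed})",
                       attributes={"label": labels})
    return cloud, truth


def generate_field(spec: FieldSpec) -> tuple[PointCloud, list[GroundTruth],
                                             list[BoundingBox]]:
    """Generate a multi-row field on a tilted, rough ground plane.

    Rows run along ``row_heading_deg`` (in the x-y plane, from the +x axis);
    the ground tilts by ``ground_slope_deg`` about the x axis. Per-point
    labels: 0 = ground, 1.. = bush index + 1, -1 = weed, -2 = scattered
    outlier.

    Returns the field cloud, per-bush truth records and per-bush bounding
    boxes, all in field coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    rows = spec.bush_specs or [[BushSpec()] * 3] * 2
    n_rows = len(rows)
    n_per = max(len(r) for r in rows)

    heading = math.radians(spec.row_heading_deg)
    u = np.array([math.cos(heading), math.sin(heading), 0.0])   # along row
    v = np.array([-math.sin(heading), math.cos(heading), 0.0])  # across rows
    slope = math.radians(spec.ground_slope_deg)
    # ground plane tilted about the x axis: z = tan(slope) * y
    margin = 2.0
    extent_u = (n_per - 1) * spec.plant_spacing_m + 2 * margin
    extent_v = (n_rows - 1) * spec.row_spacing_m + 2 * margin

    all_pts, all_labels = [], []
    truths, boxes = [], []

    # ground points over the field footprint
    n_ground = max(int(spec.ground_density * extent_u * extent_v), 100)
    gu = rng.uniform(-margin, extent_u - margin, size=n_ground)
    gv = rng.uniform(-margin, extent_v - margin, size=n_ground)
    gxy = gu[:, None] * u[None, :2] + gv[:, None] * v[None, :2]
    gz = np.tan(slope) * gxy[:, 1]
    if spec.ground_roughness_m > 0:
        gz = gz + rng.normal(scale=spec.ground_roughness_m, size=n_ground)
    all_pts.append(np.column_stack([gxy, gz]))
    all_labels.append(np.zeros(n_ground, dtype=int))

    bush_id = 0
    for i_row, row in enumerate(rows):
        for i_plant, bush_spec in enumerate(row):
            base = (i_plant * spec.plant_spacing_m * u
                    + i_row * spec.row_spacing_m * v)
            base[2] = math.tan(slope) * base[1]
            sub = BushSpec(**{**asdict(bush_spec),
                              "seed": int(rng.integers(2**31))})
            cloud, truth = generate_bush(sub)
            pts = cloud.points + base
            all_pts.append(pts)
            is_out = cloud.attributes["label"] == 2
            lab = np.where(is_out, -2, bush_id + 1)
            all_labels.append(lab)
            truth.bush_id = bush_id
            truth.box = BoundingBox(pts[~is_out].min(axis=0) - 0.15,
                                    pts[~is_out].max(axis=0) + 0.15)
            truths.append(truth)
            boxes.append(truth.box)
            bush_id += 1

    if (n_rows > 1 and spec.row_spacing_m < 1.2) or spec.plant_spacing_m < 1.0:
        warnings.warn("bush spacing is small; neighbouring bushes may overlap")

    for _ in range(spec.n_weed_clusters):
        i_row = int(rng.integers(max(n_rows - 1, 1)))
        center = (rng.uniform(0, extent_u - 2 * margin) * u
                  + (i_row + 0.5) * spec.row_spacing_m * v)
        center[2] = math.tan(slope) * center[1] + 0.1
        n_weed = int(rng.integers(50, 501))
        # low vegetation: weeds stay below the 0.3 m bush-depth threshold
        weed = center + rng.normal(scale=(0.12, 0.12, 0.05),
                                   size=(n_weed, 3))
        weed[:, 2] = np.minimum(
            np.abs(weed[:, 2] - center[2]) + center[2], center[2] + 0.18)
        all_pts.append(weed)
        all_labels.append(np.full(n_weed, -1))

    cloud = PointCloud(
        np.vstack(all_pts),
        source_id=f"synthetic_field(seed={spec.seed})",
        attributes={"label": np.concatenate(all_labels)},
    )
    return cloud, truths, boxes


def cylinder_layer_volume(cloud: PointCloud,
                          layer_interval_m: float = 0.05) -> float:
    """Reference bush volume by the stacked-cylinder protocol.

    The cloud is sliced into vertical layers of ``layer_interval_m`` (5 cm by
    default); each layer is treated as a cylinder whose diameter is the mean
    of the layer's x-extent and y-extent — the point-cloud analogue of a
    girth-tape measurement. Layer volumes are summed. Empty layers
    contribute zero.
    """
    if layer_interval_m <= 0:
        raise ValueError("layer_interval_m must be > 0")
    z = cloud.points[:, 2]
    z0, z1 = z.min(), z.max()
    n_layers = max(int(np.ceil((z1 - z0) / layer_interval_m)), 1)
    total = 0.0
    for i in range(n_layers):
        lo = z0 + i * layer_interval_m
        sel = (z >= lo) & (z < lo + layer_interval_m) if i < n_layers - 1 \
            else (z >= lo) & (z <= z1)
        if sel.sum() < 2:
            continue
        layer = cloud.points[sel]
        dia = 0.5 * ((layer[:, 0].max() - layer[:, 0].min())
                     + (layer[:, 1].max() - layer[:, 1].min()))
        total += np.pi * (dia / 2.0) ** 2 * layer_interval_m
    return float(total)
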