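"""Point-cloud containers and file I/O (LAS / PLY / XYZ / CSV), box cropping.

All coordinates are meters throughout the package. Files are read and written
with their native axes untouched; rigid alignment happens downstream in
:mod:`shrubshape.preprocess`.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import _las

__all__ = [
    "PointCloud",
    "BoundingBox",
    "read_point_cloud",
    "write_point_cloud",
    "crop_box",
    "read_boxes_csv",
    "write_boxes_csv",
]


@dataclass
class PointCloud:
    """An unordered set of 3D points in meters.

    Parameters
    ----------
    points : (N, 3) float array
        x, y, z coordinates in meters.
    source_id : str
        Free-text provenance label (file name, generator spec, ...).
    attributes : dict of str -> (N,) array
        Optional per-point annotations (e.g. generator labels).
    """

    points: np.ndarray
    source_id: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.points) == 0:
            raise ValueError("a PointCloud must contain at least one point")
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        for key, val in self.attributes.items():
            if len(val) != len(self.points):
                raise ValueError(f"attribute {key!r} length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray, source_id: str | None = None) -> "PointCloud":
        """Return the sub-cloud of points where ``mask`` is true."""
        return PointCloud(
            self.points[mask],
            source_id if source_id is not None else self.source_id,
            {k: np.asarray(v)[mask] for k, v in self.attributes.items()},
        )

    def bounds(self) -> "BoundingBox":
        return BoundingBox(self.points.min(axis=0), self.points.max(axis=0))


@dataclass
class BoundingBox:
    """Axis-aligned box given by its two extreme corners (meters)."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self):
        self.min_corner = np.asarray(self.min_corner, dtype=float)
        self.max_corner = np.asarray(self.max_corner, dtype=float)
        if self.min_corner.shape != (3,) or self.max_corner.shape != (3,):
            raise ValueError("corners must be 3-vectors")
        if np.any(self.min_corner > self.max_corner):
            raise ValueError("min_corner must be <= max_corner componentwise")


_FORMATS = ("las", "ply", "xyz", "csv")


def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise ValueError(f"unsupported point-cloud format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    if suffix in ("txt", "pts"):
        return "xyz"
    raise ValueError(f"cannot infer point-cloud format from {path.name!r}")


def read_point_cloud(path: str | Path, format: str = "auto") -> PointCloud:
    """Read a point cloud from LAS (1.x, formats 0/1), PLY, XYZ or CSV.

    Coordinates are returned in meters with (x, y, z) order preserved and no
    rescaling beyond the LAS header's own scale/offset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "las":
        pts = _las.read_las(path)
    elif fmt == "ply":
        mesh = trimesh.load(str(path), file_type="ply", process=False)
        pts = np.asarray(mesh.vertices, dtype=float)
    elif fmt in ("xyz", "csv"):
        delim = "," if fmt == "csv" else None
        skip = 1 if fmt == "csv" else 0
        try:
            pts = np.loadtxt(path, delimiter=delim, skiprows=skip, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} record ({exc})") from exc
        if pts.size and pts.shape[1] != 3:
            raise ValueError(f"{path}: expected 3 columns, found {pts.shape[1]}")
    if len(pts) == 0:
        raise ValueError(f"{path}: empty point cloud")
    return PointCloud(pts, source_id=path.name)


def write_point_cloud(cloud: PointCloud, path: str | Path,
                      format: str = "auto") -> Path:
    """Write ``cloud`` to ``path``; round-trips through :func:`read_point_cloud`.

    PLY is written as binary little-endian (``format='ply'``) — pass
    ``format='ply_ascii'`` for the ASCII dialect.
    """
    path = Path(path)
    fmt = format
    ascii_ply = fmt == "ply_ascii"
    if ascii_ply:
        fmt = "ply"
    fmt = _infer_format(path, fmt)
    if fmt == "las":
        _las.write_las(path, cloud.points)
    elif fmt == "ply":
        pc = trimesh.PointCloud(cloud.points)
        data = pc.export(file_type="ply", encoding="ascii" if ascii_ply else "binary")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    elif fmt == "xyz":
        np.savetxt(path, cloud.points, fmt="%.8f")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "z"])
            for row in cloud.points:
                writer.writerow([f"{v:.8f}" for v in row])
    return path


def crop_box(cloud: PointCloud, box: BoundingBox) -> PointCloud:
    """Return the points with min <= coord <= max on all three axes.

    Intervals are closed so that boundary points on rasterized grids are kept.
    """
    inside = np.all(
        (cloud.points >= box.min_corner) & (cloud.points <= box.max_corner),
        axis=1,
    )
    if not inside.any():
        raise ValueError(
            f"crop_box: none of the {len(cloud)} points fall inside the box "
            f"[{box.min_corner}, {box.max_corner}]"
        )
    return cloud.select(inside)


def read_boxes_csv(path: str | Path) -> list[BoundingBox]:
    """Read per-bush boxes from a CSV with columns xmin..zmin, xmax..zmax."""
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return [BoundingBox(r[:3], r[3:6]) for r in rows]


def write_boxes_csv(boxes: list[BoundingBox], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["xmin", "ymin", "zmin", "xmax", "ymax", "zmax"])
        for b in boxes:
            writer.writerow([f"{v:.6f}" for v in (*b.min_corner, *b.max_corner)])
    return path
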