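"""Minimal LAS 1.2 reader/writer for XYZ point records.

Supports point data record formats 0 and 1 (the plain XYZ formats with and
without GPS time). Coordinates are stored as scaled 32-bit integers in the
file; the header's scale and offset are applied on read so that the in-memory
cloud is always in meters.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_SIZE = 227  # LAS 1.2 public header block
_SIGNATURE = b"LASF"
# point record sizes for formats 0 and 1
_RECORD_SIZE = {0: 20, 1: 28}


class LASFormatError(ValueError):
    """Raised when a file does not parse as the supported LAS subset."""


def read_las(path: str | Path) -> np.ndarray:
    """Read an LAS 1.x file, returning an (N, 3) float64 array in meters."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise LASFormatError(f"{path}: file shorter than an LAS header")
    if raw[:4] != _SIGNATURE:
        raise LASFormatError(f"{path}: missing LASF signature")
    point_format = raw[104]
    if point_format not in _RECORD_SIZE:
        raise LASFormatError(
            f"{path}: point data format {point_format} not supported (0/1 only)"
        )
    (offset_to_points,) = struct.unpack_from("<I", raw, 96)
    (record_len,) = struct.unpack_from("<H", raw, 105)
    (n_points,) = struct.unpack_from("<I", raw, 107)
    scale = np.array(struct.unpack_from("<3d", raw, 131))
    offset = np.array(struct.unpack_from("<3d", raw, 155))
    if n_points == 0:
        raise LASFormatError(f"{path}: empty point cloud")
    end = offset_to_points + n_points * record_len
    if len(raw) < end:
        raise LASFormatError(
            f"{path}: truncated at record {(len(raw) - offset_to_points) // record_len}"
        )
    body = np.frombuffer(raw, dtype=np.uint8, count=n_points * record_len,
                         offset=offset_to_points).reshape(n_points, record_len)
    xyz_int = body[:, :12].copy().view("<i4").reshape(n_points, 3)
    return xyz_int * scale + offset


def write_las(path: str | Path, points: np.ndarray,
              scale: float = 0.001) -> None:
    """Write an (N, 3) array as an LAS 1.2 file, point format 0.

    ``scale`` is the coordinate resolution in meters (default 1 mm).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    offset = points.min(axis=0)
    xyz_int = np.round((points - offset) / scale).astype("<i4")

    header = bytearray(_HEADER_SIZE)
    header[:4] = _SIGNATURE
    struct.pack_into("<H", header, 94, _HEADER_SIZE)       # header size
    struct.pack_into("<I", header, 96, _HEADER_SIZE)       # offset to points
    header[24] = 1                                         # version major
    header[25] = 2                                         # version minor
    header[104] = 0                                        # point format
    struct.pack_into("<H", header, 105, _RECORD_SIZE[0])
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *offset)
    maxs, mins = points.max(axis=0), points.min(axis=0)
    struct.pack_into("<6d", header, 179, maxs[0], mins[0],
                     maxs[1], mins[1], maxs[2], mins[2])

    body = np.zeros((n, _RECORD_SIZE[0]), dtype=np.uint8)
    body[:, :12] = xyz_int.view(np.uint8).reshape(n, 12)
    Path(path).write_bytes(bytes(header) + body.tobytes())
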