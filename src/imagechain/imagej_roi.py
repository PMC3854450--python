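"""Minimal reader/writer for ImageJ ``.roi`` records and ROI zip archives.

Only the subset needed for training-point exchange is supported: point,
polygon, rectangle and oval ROIs.  Area ROIs (rect/oval) are reduced to
their integer centres.  ImageJ coordinates are already 0-based and are kept
as-is; the stack position field (1-based slice) maps to the 0-based z.

Record layout (big-endian), per the published ImageJ format:

    bytes 0-3   magic "Iout"
    bytes 4-5   version (short)
    byte  6     roi type (0 polygon, 1 rect, 2 oval, 10 point)
    bytes 8-15  top, left, bottom, right (shorts)
    bytes 16-17 number of coordinates
    bytes 56-59 position (int, 1-based slice; 0 = none)
    bytes 64-   n shorts of x offsets then n shorts of y offsets
                (relative to left/top)
"""

from __future__ import annotations

import struct
import zipfile
from io import BytesIO
from pathlib import Path
from typing import Iterable, List, Sequence

from .errors import FormatError
from .volume import Coordinate

_MAGIC = b"Iout"
_VERSION = 227
TYPE_POLYGON = 0
TYPE_RECT = 1
TYPE_OVAL = 2
TYPE_POINT = 10


def decode_roi(data: bytes, name: str = "<roi>") -> List[Coordinate]:
    """Decode one .roi record into a list of 0-based coordinates."""
    if len(data) < 64 or data[:4] != _MAGIC:
        raise FormatError(f"{name}: not an ImageJ ROI record")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n_coords = struct.unpack(">h", data[16:18])[0]
    position = struct.unpack(">i", data[56:60])[0]
    z = max(position - 1, 0)
    if roi_type in (TYPE_POINT, TYPE_POLYGON):
        need = 64 + 4 * n_coords
        if len(data) < need:
            raise FormatError(f"{name}: truncated coordinate block")
        xs = struct.unpack(f">{n_coords}h", data[64:64 + 2 * n_coords])
        ys = struct.unpack(
            f">{n_coords}h", data[64 + 2 * n_coords:64 + 4 * n_coords])
        return [Coordinate(left + x, top + y, z) for x, y in zip(xs, ys)]
    if roi_type in (TYPE_RECT, TYPE_OVAL):
        cx = (left + right) // 2
        cy = (top + bottom) // 2
        return [Coordinate(cx, cy, z)]
    raise FormatError(f"{name}: unsupported ROI type {roi_type}")


def encode_point_roi(coord: Coordinate) -> bytes:
    """Encode a single-point ROI record."""
    buf = bytearray(64)
    buf[0:4] = _MAGIC
    struct.pack_into(">h", buf, 4, _VERSION)
    buf[6] = TYPE_POINT
    struct.pack_into(">4h", buf, 8, coord.y, coord.x,
                     coord.y + 1, coord.x + 1)
    struct.pack_into(">h", buf, 16, 1)
    struct.pack_into(">i", buf, 56, coord.z + 1)
    buf += struct.pack(">h", 0)  # x offset relative to left
    buf += struct.pack(">h", 0)  # y offset relative to top
    return bytes(buf)


def read_imagej_roi_zip(path: str | Path) -> List[Coordinate]:
    """All coordinates from a zip archive of .roi records.

    Point/polygon ROIs contribute each of their points; rectangle and oval
    ROIs contribute their integer centres.
    """
    path = Path(path)
    if not zipfile.is_zipfile(path):
        raise FormatError(f"{path}: not a zip archive of ImageJ ROIs")
    coords: List[Coordinate] = []
    with zipfile.ZipFile(path) as zf:
        for member in sorted(zf.namelist()):
            if not member.lower().endswith(".roi"):
                continue
            try:
                coords.extend(decode_roi(zf.read(member), name=member))
            except FormatError:
                raise
            except Exception as exc:  # corrupt member
                raise FormatError(f"{member}: corrupt ROI record: {exc}")
    return coords


def write_imagej_roi_zip(path: str | Path,
                         coords: Sequence[Coordinate]) -> None:
    """Write each coordinate as one point ROI member of a zip archive."""
    path = Path(path)
    with zipfile.ZipFile(path, "w") as zf:
        for i, c in enumerate(coords):
            zf.writestr(f"{i:04d}-{c.y:04d}-{c.x:04d}.roi",
                        encode_point_roi(c))
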