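"""Vaa3D marker/landmark file reader and writer.

The format is comma-separated text, one marker per line:
``x, y, z, radius, shape, name, comment``; '#' lines are comments.  Marker
coordinates are 1-based in Vaa3D and are shifted by -1 on read (+1 on
write) to the package's 0-based convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

from .errors import FormatError
from .volume import Coordinate


def read_vaa3d_marker(path: str | Path) -> List[Coordinate]:
    coords: List[Coordinate] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(",")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: expected at least x,y,z fields")
        try:
            x, y, z = (int(round(float(fields[i]))) for i in range(3))
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric coordinate field")
        coords.append(Coordinate(x - 1, y - 1, z - 1))
    return coords


def write_vaa3d_marker(path: str | Path, coords: Sequence[Coordinate],
                       name: str = "", comment: str = "") -> None:
    lines = ["#x,y,z,radius,shape,name,comment"]
    for c in coords:
        lines.append(f"{c.x + 1},{c.y + 1},{c.z + 1},0,1,{name},{comment}")
    Path(path).write_text("\n".join(lines) + "\n")
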