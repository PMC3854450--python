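"""In-memory image container and patch geometry.

Conventions
-----------
* Coordinates are 0-based ``(x, y, z)`` voxel indices, x being the fastest
  axis.  A 2D image has ``nz == 1`` and ``z == 0``.
* Voxel data is stored as a float array of shape ``(nz, ny, nx)`` (slice,
  row, column), matching how multi-page TIFF stacks are laid out on disk.
* Intensities are held as real numbers; integer inputs are not rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Tuple, Union

import numpy as np

from .errors import ArgumentError

Channel = Union[str, int]  # "all", "red", "green", "blue" or a channel index


@dataclass(frozen=True)
class Coordinate:
    """0-based voxel index (x, y, z); z = 0 for 2D images."""

    x: int
    y: int
    z: int = 0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.z < 0:
            raise ArgumentError(f"coordinate must be non-negative, got {self}")

    def as_tuple(self) -> Tuple[int, int, int]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class PatchGeometry:
    """Half-widths of an ROI patch spanning (2rx+1) x (2ry+1) x (2rz+1) voxels."""

    rx: int
    ry: int
    rz: int = 0

    def __post_init__(self) -> None:
        if self.rx < 0 or self.ry < 0 or self.rz < 0:
            raise ArgumentError(f"half-widths must be non-negative, got {self}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        """(nz, ny, nx) shape of the patch."""
        return (2 * self.rz + 1, 2 * self.ry + 1, 2 * self.rx + 1)


@dataclass
class ImageVolume:
    """A 2D/3D grid of non-negative real intensities.

    ``data`` has shape (nz, ny, nx); ``data[z, y, x]`` is the intensity
    I(x, y, z).
    """

    data: np.ndarray
    source_path: str | None = None
    channel: Channel = "all"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise ArgumentError(f"expected 2D or 3D data, got ndim={arr.ndim}")
        if arr.size == 0:
            raise ArgumentError("empty image")
        if not np.all(np.isfinite(arr)):
            raise ArgumentError("image intensities must be finite")
        if arr.min() < 0:
            raise ArgumentError("image intensities must be non-negative")
        self.data = arr

    @property
    def nx(self) -> int:
        return self.data.shape[2]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nz(self) -> int:
        return self.data.shape[0]

    @property
    def is_2d(self) -> bool:
        return self.nz == 1

    def value_at(self, c: Coordinate) -> float:
        return float(self.data[c.z, c.y, c.x])

    def contains(self, c: Coordinate) -> bool:
        return c.x < self.nx and c.y < self.ny and c.z < self.nz

    def plane(self, z: int = 0) -> np.ndarray:
        """The (ny, nx) intensity plane of slice z."""
        return self.data[z]

    def crop(self, x0: int, x1: int, y0: int, y1: int,
             z0: int = 0, z1: int | None = None) -> "ImageVolume":
        z1 = self.nz if z1 is None else z1
        return ImageVolume(self.data[z0:z1, y0:y1, x0:x1].copy(),
                           source_path=self.source_path, channel=self.channel)


def extract_patch(volume: ImageVolume, center: Coordinate,
                  geometry: PatchGeometry) -> np.ndarray:
    """Extract the (2rz+1, 2ry+1, 2rx+1) patch centred on ``center``.

    Out-of-bounds voxels are zero-filled (dark-background convention), so
    border centres are valid.
    """
    if not volume.contains(center):
        raise ArgumentError(
            f"center {center.as_tuple()} outside volume "
            f"({volume.nx}x{volume.ny}x{volume.nz})")
    nz, ny, nx = geometry.shape
    patch = np.zeros((nz, ny, nx), dtype=float)
    z0, y0, x0 = (center.z - geometry.rz, center.y - geometry.ry,
                  center.x - geometry.rx)
    zs0, ys0, xs0 = max(z0, 0), max(y0, 0), max(x0, 0)
    zs1 = min(z0 + nz, volume.nz)
    ys1 = min(y0 + ny, volume.ny)
    xs1 = min(x0 + nx, volume.nx)
    patch[zs0 - z0:zs1 - z0, ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = \
        volume.data[zs0:zs1, ys0:ys1, xs0:xs1]
    return patch


def patch_as_volume(patch: np.ndarray) -> ImageVolume:
    """Wrap a patch array as an ImageVolume so extractors apply uniformly."""
    return ImageVolume(patch)


def coordinates_in_bounds(coords: Iterable[Coordinate],
                          volume: ImageVolume) -> bool:
    return all(volume.contains(c) for c in coords)
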