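"""Image reading and the three label-association input modes.

Training labels can be attached to images in three ways:

* ``target-file``: a text file of whitespace-separated
  ``image-name label [label ...]`` lines (multi-label allowed);
* ``directory-tree``: one immediate subdirectory per class;
* ``roi``: ImageJ ROI zip / Vaa3D marker files over one image, where each
  file's base name is the class name (``pos.zip`` -> class ``pos``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import ArgumentError, DataError, FormatError
from .imagej_roi import read_imagej_roi_zip
from .vaa3d import read_vaa3d_marker
from .volume import Channel, Coordinate, ImageVolume, PatchGeometry

IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}

_RGB_NAMES = {"red": 0, "green": 1, "blue": 2}


def _select_channel(arr: np.ndarray, channel: Channel) -> np.ndarray:
    """Collapse or pick the channel axis of a (..., ny, nx[, c]) array."""
    has_channels = arr.ndim >= 3 and arr.shape[-1] in (3, 4) and \
        arr.shape[-1] < min(arr.shape[-3:-1])
    if not has_channels:
        if channel == "all":
            return arr
        raise ArgumentError(
            f"channel {channel!r} requested but image is single-channel")
    if channel == "all":
        return arr[..., :3].mean(axis=-1)
    if isinstance(channel, str):
        if channel not in _RGB_NAMES:
            raise ArgumentError(f"unknown channel name {channel!r}")
        idx = _RGB_NAMES[channel]
    else:
        idx = int(channel)
    if idx >= arr.shape[-1]:
        raise ArgumentError(
            f"channel index {idx} out of range for {arr.shape[-1]} channels")
    return arr[..., idx]


def read_image_volume(path: str | Path,
                      channel: Channel = "all") -> ImageVolume:
    """Read a PNG or (multi-page) TIFF into an ImageVolume.

    A 2D image loads with nz = 1; a k-page TIFF with nz = k.  For
    multi-channel input only the selected channel is kept ("all" averages
    RGB); integer intensities are preserved bit-exactly (no rescaling).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"image not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}")
    arr = np.asarray(arr)
    arr = _select_channel(arr, channel)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(f"{path}: unsupported image dimensionality")
    return ImageVolume(arr.astype(float), source_path=str(path),
                       channel=channel)


@dataclass
class LabeledImageSet:
    """Image references with their (possibly multi-) label sets."""

    entries: List[Tuple[str, Set[str]]]
    classes: List[str]
    mode: str  # "target-file" | "directory-tree" | "roi"
    root: Optional[str] = None
    channel: Channel = "all"

    def __post_init__(self) -> None:
        class_set = set(self.classes)
        for ref, labels in self.entries:
            if not labels:
                raise ArgumentError(f"entry {ref!r} has an empty label set")
            if not labels <= class_set:
                raise ArgumentError(
                    f"entry {ref!r} carries labels outside the class list")

    @property
    def single_label(self) -> bool:
        return all(len(labels) == 1 for _, labels in self.entries)

    def load_image(self, ref: str) -> ImageVolume:
        path = Path(ref)
        if not path.is_absolute() and self.root is not None:
            path = Path(self.root) / path
        return read_image_volume(path, channel=self.channel)


@dataclass
class ROISet:
    """Labelled point ROIs over one image, sharing one patch geometry."""

    image_path: str
    points: List[Tuple[Coordinate, str]]
    geometry: PatchGeometry
    classes: List[str] = field(default_factory=list)
    channel: Channel = "all"

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted({lbl for _, lbl in self.points})

    def load_image(self) -> ImageVolume:
        return read_image_volume(self.image_path, channel=self.channel)

    def validate_bounds(self, volume: ImageVolume) -> None:
        for c, lbl in self.points:
            if not volume.contains(c):
                raise ArgumentError(
                    f"ROI point {c.as_tuple()} (class {lbl!r}) outside "
                    f"image bounds")


def _read_target_file(target_file: Path, root: Path,
                      channel: Channel) -> LabeledImageSet:
    entries: List[Tuple[str, Set[str]]] = []
    missing: List[str] = []
    classes: Set[str] = set()
    for raw in target_file.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(
                f"{target_file}: line {line!r} needs image-name and labels")
        name, labels = parts[0], set(parts[1:])
        if not (root / name).exists():
            missing.append(name)
        entries.append((name, labels))
        classes |= labels
    if missing:
        raise DataError(
            f"target file references missing images: {sorted(missing)}")
    return LabeledImageSet(entries=entries, classes=sorted(classes),
                           mode="target-file", root=str(root),
                           channel=channel)


def _read_directory_tree(root: Path, channel: Channel) -> LabeledImageSet:
    entries: List[Tuple[str, Set[str]]] = []
    classes: List[str] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        images = sorted(p for p in sub.iterdir()
                        if p.suffix.lower() in IMAGE_SUFFIXES)
        if not images:
            warnings.warn(f"class directory {sub.name!r} is empty; dropped")
            continue
        classes.append(sub.name)
        for img in images:
            entries.append((f"{sub.name}/{img.name}", {sub.name}))
    return LabeledImageSet(entries=entries, classes=classes,
                           mode="directory-tree", root=str(root),
                           channel=channel)


def _read_roi_mode(image_path: Path, roi_files: Sequence[Path],
                   geometry: PatchGeometry, channel: Channel) -> ROISet:
    points: List[Tuple[Coordinate, str]] = []
    for rf in sorted(roi_files):
        label = rf.stem
        if rf.suffix.lower() == ".zip":
            coords = read_imagej_roi_zip(rf)
        elif rf.suffix.lower() == ".marker":
            coords = read_vaa3d_marker(rf)
        else:
            raise FormatError(f"unsupported ROI file type: {rf}")
        points.extend((c, label) for c in coords)
    roi_set = ROISet(image_path=str(image_path), points=points,
                     geometry=geometry, channel=channel)
    roi_set.validate_bounds(roi_set.load_image())
    return roi_set


def load_labeled_set(mode: str, path: str | Path, *,
                     target_file: str | Path | None = None,
                     image: str | Path | None = None,
                     roi_files: Sequence[str | Path] | None = None,
                     geometry: PatchGeometry | None = None,
                     channel: Channel = "all"
                     ) -> Union[LabeledImageSet, ROISet]:
    """Load training labels in one of the three association modes.

    mode="directory-tree": ``path`` is the tree root.
    mode="target-file": ``path`` is the image root, ``target_file`` the
    label file (defaults to ``path/targets.txt``).
    mode="roi": ``image`` is the annotated image, ``roi_files`` the ROI
    zip / marker files (class = file base name), ``geometry`` the shared
    patch geometry; ``path`` is the directory scanned for ROI files when
    ``roi_files`` is not given.
    """
    path = Path(path)
    if mode == "directory-tree":
        return _read_directory_tree(path, channel)
    if mode == "target-file":
        tf = Path(target_file) if target_file else path / "targets.txt"
        if not tf.exists():
            raise DataError(f"target file not found: {tf}")
        return _read_target_file(tf, path, channel)
    if mode == "roi":
        if geometry is None:
            raise ArgumentError("roi mode requires a patch geometry")
        if roi_files is None:
            roi_files = [p for p in sorted(path.iterdir())
                         if p.suffix.lower() in {".zip", ".marker"}]
        if image is None:
            candidates = [p for p in sorted(path.iterdir())
                          if p.suffix.lower() in IMAGE_SUFFIXES]
            if len(candidates) != 1:
                raise ArgumentError(
                    "roi mode needs an explicit image when the directory "
                    f"holds {len(candidates)} image files")
            image = candidates[0]
        return _read_roi_mode(Path(image), [Path(p) for p in roi_files],
                              geometry, channel)
    raise ArgumentError(
        f"unknown mode {mode!r}; one of directory-tree, target-file, roi")
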