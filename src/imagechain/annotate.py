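"""Applying a trained model to new images.

Sliding-window annotation classifies the patch around every lattice site
(every ``interval``-th voxel per axis; interval 1 annotates every voxel).
For mostly-dark 3D stacks the decision sites can be restricted to the
image's local intensity maxima (computed by grayscale morphological
dilation), and object counts are obtained by mean-shifting the positively
classified sites to their intensity modes and merging nearby centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .chains import TrainedModel
from .errors import ArgumentError, ContractError
from .io import LabeledImageSet
from .volume import Coordinate, ImageVolume


@dataclass(frozen=True)
class SlidingSpec:
    """Voxels between successive classification decisions (default 1)."""

    interval: int = 1

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ArgumentError("interval must be >= 1")


@dataclass(frozen=True)
class MaximaSpec:
    """Structuring-element half-width and intensity floor for maxima.

    The floor defaults to the image's Otsu threshold (None).
    """

    radius: int = 1
    floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ArgumentError("radius must be >= 1")


@dataclass
class AnnotationGrid:
    decisions: List[Tuple[Coordinate, str, Optional[float]]]
    interval: int
    source_path: Optional[str] = None

    def labels(self) -> List[str]:
        return [lbl for _, lbl, _ in self.decisions]

    def coordinates_for(self, label: str) -> List[Coordinate]:
        return [c for c, lbl, _ in self.decisions if lbl == label]

    def to_mask(self, volume: ImageVolume,
                class_order: Sequence[str]) -> np.ndarray:
        """Label-indexed mask (0 = undecided, i+1 = class_order[i])."""
        mask = np.zeros(volume.data.shape, dtype=np.uint8)
        index = {c: i + 1 for i, c in enumerate(class_order)}
        for c, lbl, _ in self.decisions:
            mask[c.z, c.y, c.x] = index.get(lbl, 0)
        return mask


def local_maxima(volume: ImageVolume,
                 spec: MaximaSpec = MaximaSpec()) -> List[Coordinate]:
    """Voxels whose intensity equals the grayscale dilation of the image
    under the cubic structuring element and exceeds the intensity floor.

    A constant plateau of maxima is deduplicated to its lexicographically
    smallest (x, y, z) coordinate.  Results are sorted by (x, y, z).
    """
    data = volume.data
    floor = spec.floor
    if floor is None:
        floor = float(threshold_otsu(data.ravel())) if np.ptp(data) > 0 \
            else float(data.ravel()[0])
    size = 2 * spec.radius + 1
    footprint = (1, size, size) if volume.is_2d else (size, size, size)
    dilated = ndi.grey_dilation(data, size=footprint, mode="constant")
    mask = (data == dilated) & (data > floor)
    if not mask.any():
        return []
    # adjacent maxima necessarily share one value -> components are plateaus
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndi.label(mask, structure=structure)
    coords: List[Coordinate] = []
    for i in range(1, n + 1):
        zz, yy, xx = np.nonzero(labels == i)
        pts = sorted(zip(xx.tolist(), yy.tolist(), zz.tolist()))
        x, y, z = pts[0]
        coords.append(Coordinate(x, y, z))
    return sorted(coords, key=lambda c: c.as_tuple())


def lattice_sites(volume: ImageVolume, interval: int) -> List[Coordinate]:
    """The decision lattice {0, interval, 2*interval, ...} per axis."""
    return [Coordinate(x, y, z)
            for z in range(0, volume.nz, interval)
            for y in range(0, volume.ny, interval)
            for x in range(0, volume.nx, interval)]


def sliding_annotate(model: TrainedModel, volume: ImageVolume,
                     spec: SlidingSpec = SlidingSpec(),
                     restrict_to: Optional[Sequence[Coordinate]] = None
                     ) -> AnnotationGrid:
    """Classify the ROI patch around each decision site.

    Sites are the interval lattice, or ``restrict_to`` (e.g. local maxima)
    when given.  Border sites use zero-padded patches, so at interval 1
    every voxel receives a decision.
    """
    if model.geometry is None:
        raise ContractError(
            "model carries no patch geometry; train it on an ROI set")
    geom = model.geometry
    if volume.nx < 2 * geom.rx + 1 or volume.ny < 2 * geom.ry + 1:
        raise ArgumentError("volume smaller than one model patch")
    sites = list(restrict_to) if restrict_to is not None \
        else lattice_sites(volume, spec.interval)
    from .volume import extract_patch, patch_as_volume
    patches = [patch_as_volume(extract_patch(volume, c, geom))
               for c in sites]
    decisions: List[Tuple[Coordinate, str, Optional[float]]] = []
    if patches:
        labels = model.predict_volumes(patches)
        decisions = [(c, lbl, None) for c, lbl in zip(sites, labels)]
    return AnnotationGrid(decisions=decisions, interval=spec.interval,
                          source_path=volume.source_path)


def _ball_offsets(radius: float, is_2d: bool) -> np.ndarray:
    r = int(np.ceil(radius))
    zs = [0] if is_2d else range(-r, r + 1)
    offs = [(x, y, z)
            for z in zs for y in range(-r, r + 1) for x in range(-r, r + 1)
            if x * x + y * y + z * z <= radius * radius]
    return np.array(offs, dtype=float)


def mean_shift(volume: ImageVolume, start: Coordinate, radius: float,
               tol: float = 0.5, max_iter: int = 50) -> np.ndarray:
    """Iterate a point to the intensity-weighted centroid of its
    radius-neighbourhood until displacement < ``tol`` voxels."""
    offs = _ball_offsets(radius, volume.is_2d)
    pos = np.array(start.as_tuple(), dtype=float)
    bounds = np.array([volume.nx, volume.ny, volume.nz], dtype=float) - 1
    for _ in range(max_iter):
        pts = np.round(pos + offs).astype(int)
        ok = np.all((pts >= 0) & (pts <= bounds), axis=1)
        pts = pts[ok]
        w = volume.data[pts[:, 2], pts[:, 1], pts[:, 0]]
        total = w.sum()
        if total <= 0:
            break
        new = (pts * w[:, None]).sum(axis=0) / total
        if np.linalg.norm(new - pos) < tol:
            pos = new
            break
        pos = new
    return pos


def merge_centers(candidates: Sequence[Coordinate], volume: ImageVolume,
                  merge_radius: float = 3.0,
                  window_radius: Optional[float] = None
                  ) -> Tuple[int, List[Coordinate]]:
    """Mean-shift candidates to their intensity modes, then merge nearby
    converged points (single linkage at ``merge_radius``).

    Each cluster contributes one centre (the intensity-weighted mean of its
    converged points); the count is the cluster count.
    """
    if not candidates:
        return 0, []
    for c in candidates:
        if not volume.contains(c):
            raise ArgumentError(f"candidate {c.as_tuple()} outside volume")
    if window_radius is None:
        window_radius = merge_radius
    converged = np.array([mean_shift(volume, c, window_radius)
                          for c in candidates])
    n = len(converged)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(converged[i] - converged[j]) < merge_radius:
                parent[find(i)] = find(j)
    clusters: Dict[int, List[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    centers: List[Coordinate] = []
    bounds = np.array([volume.nx, volume.ny, volume.nz]) - 1
    for members in clusters.values():
        pts = converged[members]
        ipts = np.clip(np.round(pts).astype(int), 0, bounds)
        w = volume.data[ipts[:, 2], ipts[:, 1], ipts[:, 0]]
        if w.sum() <= 0:
            w = np.ones(len(members))
        mean = (pts * w[:, None]).sum(axis=0) / w.sum()
        ix, iy, iz = np.clip(np.round(mean).astype(int), 0, bounds)
        centers.append(Coordinate(int(ix), int(iy), int(iz)))
    centers.sort(key=lambda c: c.as_tuple())
    return len(centers), centers


def multilabel_annotate(models: Dict[str, TrainedModel],
                        targets: Union[LabeledImageSet,
                                       Sequence[ImageVolume]],
                        positive_suffix: str = "present"
                        ) -> List[Tuple[str, List[str]]]:
    """Run one binary present/absent model per label over whole images.

    A label enters an image's set iff its model predicts the positive
    class (the class named after the label itself, or ``positive_suffix``).
    Every image is listed, including those with an empty label set.
    """
    for label, model in models.items():
        if len(model.classes) != 2:
            raise ContractError(
                f"model for label {label!r} has {len(model.classes)} "
                "classes; multi-label annotation needs binary models")
    if isinstance(targets, LabeledImageSet):
        volumes = [targets.load_image(ref) for ref, _ in targets.entries]
        names = [ref for ref, _ in targets.entries]
    else:
        volumes = list(targets)
        names = [v.source_path or f"image-{i}"
                 for i, v in enumerate(volumes)]
    report: List[Tuple[str, List[str]]] = [(n, []) for n in names]
    for label in sorted(models):
        model = models[label]
        positive = label if label in model.classes else positive_suffix
        if positive not in model.classes:
            raise ContractError(
                f"model for {label!r} has classes {model.classes}; "
                f"cannot identify the positive class")
        preds = model.predict_volumes(volumes)
        for i, p in enumerate(preds):
            if p == positive:
                report[i][1].append(label)
    return report
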