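"""Binary object segmentation and object-level statistics.

Foreground objects are connected components of the thresholded image under
full connectivity: 8-connected in 2D, 26-connected in 3D (diagonal
neighbours count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import ArgumentError
from .volume import ImageVolume


@dataclass
class BinaryObjects:
    """Labelled foreground components of an image.

    ``labels`` is an integer grid (0 = background, 1..n_components);
    ``source`` keeps the intensity image so statistics can use the
    intensity centre of mass.
    """

    mask: np.ndarray
    labels: np.ndarray
    n_components: int
    connectivity: int  # 8 (2D) or 26 (3D)
    source: Optional[ImageVolume] = None

    def component_coordinates(self, i: int) -> np.ndarray:
        """(k, 3) array of (x, y, z) voxel indices of component i (1-based)."""
        zz, yy, xx = np.nonzero(self.labels == i)
        return np.stack([xx, yy, zz], axis=1)

    def component_sizes(self) -> np.ndarray:
        return np.array([(self.labels == i).sum()
                         for i in range(1, self.n_components + 1)])


def segment_objects(image: ImageVolume,
                    threshold: Union[str, float] = "otsu") -> BinaryObjects:
    """Threshold then label under 8-/26-connectivity.

    ``threshold`` is "otsu" (parameter-free default) or a fixed number;
    foreground is intensity strictly above the threshold.  An all-background
    result is valid and yields zero components.
    """
    data = image.data
    if threshold == "otsu":
        flat = data.ravel()
        if np.ptp(flat) == 0:
            t = flat[0]  # constant image: everything is background
        else:
            t = float(threshold_otsu(flat))
    elif isinstance(threshold, (int, float)):
        t = float(threshold)
    else:
        raise ArgumentError(f"unknown threshold {threshold!r}")
    mask3 = data > t
    if image.is_2d:
        structure = np.ones((3, 3), dtype=bool)
        labels2, n = ndi.label(mask3[0], structure=structure)
        labels = labels2[None, :, :]
        conn = 8
    else:
        structure = np.ones((3, 3, 3), dtype=bool)
        labels, n = ndi.label(mask3, structure=structure)
        conn = 26
    return BinaryObjects(mask=mask3, labels=labels, n_components=int(n),
                         connectivity=conn, source=image)


def object_territory(objects: BinaryObjects) -> np.ndarray:
    """Overall foreground territory: total foreground voxel count (length 1)."""
    return np.array([float(objects.mask.sum())])


def object_statistics(objects: BinaryObjects) -> np.ndarray:
    """The 7 object statistics, in fixed order.

    1. number of objects
    2. mean object size (voxel count)
    3. variance of object sizes (population variance)
    4. mean distance from object centroids to the image's intensity centre
       of mass
    5. variance of those distances
    6. size ratio largest/smallest
    7. centroid-distance ratio furthest/closest

    Distances are Euclidean in voxel units; component centroids are binary
    (unweighted), the image reference point is the intensity centre of mass.
    Zero components yields an all-zero vector with a warning.
    """
    n = objects.n_components
    if n == 0:
        warnings.warn("no foreground objects; object statistics are all zero")
        return np.zeros(7)
    sizes = objects.component_sizes().astype(float)
    if objects.source is not None:
        data = objects.source.data
        total = data.sum()
        if total > 0:
            zs, ys, xs = np.mgrid[0:data.shape[0], 0:data.shape[1],
                                  0:data.shape[2]]
            com = np.array([(xs * data).sum(), (ys * data).sum(),
                            (zs * data).sum()]) / total
        else:
            com = (np.array(data.shape)[::-1] - 1) / 2.0
    else:
        com = (np.array(objects.mask.shape)[::-1] - 1) / 2.0
    dists = np.empty(n)
    for i in range(1, n + 1):
        coords = objects.component_coordinates(i)
        centroid = coords.mean(axis=0)
        dists[i - 1] = np.linalg.norm(centroid - com)
    closest = dists.min()
    ratio_dist = dists.max() / closest if closest > 0 else 0.0
    return np.array([
        float(n),
        sizes.mean(),
        sizes.var(),
        dists.mean(),
        dists.var(),
        sizes.max() / sizes.min(),
        ratio_dist,
    ])
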