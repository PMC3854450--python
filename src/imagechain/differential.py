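"""Gaussian-derivative, Laplacian and Hessian-eigenvalue features.

Hessian eigenvalues are the standard cue for tube-like structures (axons,
vessels): on a bright ridge one eigenvalue is large in magnitude (across
the ridge) while the other(s) stay small.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import ArgumentError
from .volume import Coordinate, ImageVolume


def _gauss(arr, sigma, order):
    # truncate=6 keeps the second-derivative kernels summing to ~0, so a
    # constant image yields (numerically) zero differential features
    return ndi.gaussian_filter(arr, sigma, order=order, truncate=6.0)


def _derivative_maps(image: ImageVolume, sigma: float
                     ) -> Tuple[List[np.ndarray], List[str]]:
    """Per-voxel maps at one scale: first derivatives, Laplacian,
    Hessian eigenvalues sorted descending."""
    if image.is_2d:
        plane = image.plane(0)
        if min(plane.shape) <= 4 * sigma:
            raise ArgumentError(
                f"scale {sigma} too large for image of shape {plane.shape}")
        dx = _gauss(plane, sigma, (0, 1))
        dy = _gauss(plane, sigma, (1, 0))
        dxx = _gauss(plane, sigma, (0, 2))
        dyy = _gauss(plane, sigma, (2, 0))
        dxy = _gauss(plane, sigma, (1, 1))
        lap = dxx + dyy
        hess = np.stack([np.stack([dxx, dxy], -1),
                         np.stack([dxy, dyy], -1)], -2)
        eigs = np.linalg.eigvalsh(hess)[..., ::-1]  # descending
        maps = [dx[None], dy[None], lap[None],
                eigs[..., 0][None], eigs[..., 1][None]]
        names = ["dx", "dy", "laplacian", "hess-eig1", "hess-eig2"]
    else:
        vol = image.data
        if min(vol.shape[1:]) <= 4 * sigma:  # x-y extent; z may be thin
            raise ArgumentError(
                f"scale {sigma} too large for volume of shape {vol.shape}")
        # axis order of arrays is (z, y, x)
        dx = _gauss(vol, sigma, (0, 0, 1))
        dy = _gauss(vol, sigma, (0, 1, 0))
        dz = _gauss(vol, sigma, (1, 0, 0))
        second = {}
        for name, order in (("xx", (0, 0, 2)), ("yy", (0, 2, 0)),
                            ("zz", (2, 0, 0)), ("xy", (0, 1, 1)),
                            ("xz", (1, 0, 1)), ("yz", (1, 1, 0))):
            second[name] = _gauss(vol, sigma, order)
        lap = second["xx"] + second["yy"] + second["zz"]
        hess = np.stack([
            np.stack([second["xx"], second["xy"], second["xz"]], -1),
            np.stack([second["xy"], second["yy"], second["yz"]], -1),
            np.stack([second["xz"], second["yz"], second["zz"]], -1),
        ], -2)
        eigs = np.linalg.eigvalsh(hess)[..., ::-1]
        maps = [dx, dy, dz, lap,
                eigs[..., 0], eigs[..., 1], eigs[..., 2]]
        names = ["dx", "dy", "dz", "laplacian",
                 "hess-eig1", "hess-eig2", "hess-eig3"]
    return maps, names


def differential_features(image: ImageVolume,
                          scales: Sequence[float] = (1.0, 2.0),
                          pooling: str = "image-stats",
                          at: Coordinate | None = None
                          ) -> Tuple[np.ndarray, List[str]]:
    """Differential features over one or more Gaussian scales.

    pooling="image-stats": mean and standard deviation of every map
    (whole-image mode); pooling="at-center": map values at coordinate
    ``at`` (ROI mode).  Output length depends only on (scales,
    dimensionality, pooling).
    """
    if not scales:
        raise ArgumentError("at least one scale required")
    values: List[float] = []
    tags: List[str] = []
    for sigma in scales:
        maps, names = _derivative_maps(image, sigma)
        for m, name in zip(maps, names):
            if pooling == "image-stats":
                values.extend([float(m.mean()), float(m.std())])
                tags.extend([f"diff/s{sigma}/{name}:mean",
                             f"diff/s{sigma}/{name}:std"])
            elif pooling == "at-center":
                c = at if at is not None else Coordinate(
                    image.nx // 2, image.ny // 2, image.nz // 2)
                values.append(float(m[c.z, c.y, c.x]))
                tags.append(f"diff/s{sigma}/{name}@center")
            else:
                raise ArgumentError(f"unknown pooling {pooling!r}")
    return np.asarray(values), tags


def hessian_eigenvalues_2d(image: ImageVolume, sigma: float = 1.0
                           ) -> np.ndarray:
    """Per-pixel 2D Hessian eigenvalues, shape (ny, nx, 2), descending."""
    maps, _ = _derivative_maps(image, sigma)
    return np.stack([maps[-2][0], maps[-1][0]], axis=-1)
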