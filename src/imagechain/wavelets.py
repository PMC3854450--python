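"""Haar wavelet texture features, including the 3D anisotropic extractor.

The 3D anisotropic wavelet feature of a voxel (x, y, z) is computed from its
surrounding (2rx+1) x (2ry+1) x (2rz+1) patch:

    f_{k,n}(x, y, z) = sum_{zi} w(zi) sum_{yi} sum_{xi}
                           psi_{k,n}(xi, yi) I(xi, yi, zi)

where psi_{k,n} is the 2D discrete Haar basis (k the dilation level, n the
translation index) and w is a Gaussian over slice offset, heaviest at the
central slice and normalised to sum 1.  By linearity this equals the 2D
multi-level Haar transform of the Gaussian-weighted z-collapse of the patch,
which is how it is evaluated here.  The feature count is quadratic in the
patch side rather than cubic, which is the point: confocal stacks have
coarser z than x-y resolution, so the z axis is collapsed instead of being
transformed.

Numerical conventions (fixed so that saved models are portable):

* Orthonormal Haar filters (1/sqrt(2) scaling): energy is conserved, i.e.
  sum of squared coefficients equals sum of squared pixels for exact
  power-of-two inputs.
* Detail = (first - second)/sqrt(2) for each sample pair.
* Odd side lengths are edge-replicated on the high side to the next even
  size, independently at every level; replication keeps a constant patch
  constant, so detail coefficients of flat regions stay exactly zero.
* Flattening order: coarsest LL block first (row-major), then per level from
  coarsest to finest the LH (row-detail), HL (column-detail), HH blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ArgumentError, ConfigurationError
from .volume import Coordinate, ImageVolume, PatchGeometry, extract_patch

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class WaveletSpec:
    """Number of dilation levels of the Haar decomposition (basis is Haar)."""

    levels: int = 2

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ArgumentError(f"levels must be >= 1, got {self.levels}")


@dataclass(frozen=True)
class ZWeighting:
    """Gaussian slice weights w(zi) over offsets -rz..rz, summing to 1."""

    sigma: float
    weights: Tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 1 or len(w) % 2 != 1:
            raise ArgumentError("weights must cover symmetric offsets -rz..rz")
        if not np.allclose(w, w[::-1]):
            raise ArgumentError("weights must be symmetric about offset 0")
        if w[len(w) // 2] < w.max() - 1e-12:
            raise ArgumentError("central slice must carry the maximum weight")
        if not np.isclose(w.sum(), 1.0):
            raise ArgumentError("weights must sum to 1")


def gaussian_z_weights(rz: int, sigma: float | None = None) -> ZWeighting:
    """Normalised Gaussian weights over slice offsets -rz..rz.

    Default spread sigma = max(rz, 1)/2 keeps the central slice dominant
    while still mixing in the neighbouring slices.
    """
    if sigma is None:
        sigma = max(rz, 1) / 2.0
    if sigma <= 0:
        raise ArgumentError("sigma must be positive")
    offs = np.arange(-rz, rz + 1, dtype=float)
    w = np.exp(-offs ** 2 / (2.0 * sigma ** 2))
    w /= w.sum()
    return ZWeighting(sigma=sigma, weights=tuple(w))


def _pad_even(plane: np.ndarray) -> np.ndarray:
    """Edge-replicate odd sides on the high side to the next even size."""
    py = plane.shape[0] % 2
    px = plane.shape[1] % 2
    if py or px:
        plane = np.pad(plane, ((0, py), (0, px)), mode="edge")
    return plane


def _haar_step(plane: np.ndarray) -> Tuple[np.ndarray, np.ndarray,
                                           np.ndarray, np.ndarray]:
    """One separable orthonormal Haar analysis step -> (LL, LH, HL, HH)."""
    plane = _pad_even(plane)
    # columns (x direction)
    lo = (plane[:, 0::2] + plane[:, 1::2]) / _SQRT2
    hi = (plane[:, 0::2] - plane[:, 1::2]) / _SQRT2
    # rows (y direction)
    ll = (lo[0::2, :] + lo[1::2, :]) / _SQRT2
    lh = (lo[0::2, :] - lo[1::2, :]) / _SQRT2
    hl = (hi[0::2, :] + hi[1::2, :]) / _SQRT2
    hh = (hi[0::2, :] - hi[1::2, :]) / _SQRT2
    return ll, lh, hl, hh


def max_levels(shape: Tuple[int, int]) -> int:
    """Admissible decomposition depth for a plane of the given (ny, nx)."""
    n = min(shape)
    lv = 0
    while n >= 2:
        n = (n + 1) // 2
        lv += 1
    return lv


def haar_decompose(plane: np.ndarray, levels: int
                   ) -> Tuple[np.ndarray, List[Tuple[np.ndarray, np.ndarray,
                                                     np.ndarray]]]:
    """Multi-level decomposition -> (LL, [(LH, HL, HH)] coarsest first)."""
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ArgumentError("expected a 2D plane")
    if levels < 1:
        raise ArgumentError("levels must be >= 1")
    if levels > max_levels(plane.shape):
        raise ArgumentError(
            f"levels={levels} exceeds admissible depth "
            f"{max_levels(plane.shape)} for shape {plane.shape}")
    details: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    ll = plane
    for _ in range(levels):
        ll, lh, hl, hh = _haar_step(ll)
        details.append((lh, hl, hh))
    details.reverse()  # coarsest first
    return ll, details


def haar_dwt_2d(plane: np.ndarray, levels: int) -> np.ndarray:
    """Multi-level 2D Haar transform as a single coefficient image.

    The output has the zero-padded input's element count, with the nested
    block layout [LL HL; LH HH], level l+1 replacing the LL block of level l.
    """
    ll, details = haar_decompose(plane, levels)
    # assemble finest-first
    out = ll
    for lh, hl, hh in details:
        top = np.hstack([out, hl])
        bottom = np.hstack([lh, hh])
        out = np.vstack([top, bottom])
    return out


def flatten_coefficients(ll: np.ndarray,
                         details: Sequence[Tuple[np.ndarray, np.ndarray,
                                                 np.ndarray]]
                         ) -> Tuple[np.ndarray, List[str]]:
    """Documented fixed flattening: LL first, then LH, HL, HH coarsest first."""
    parts = [ll.ravel()]
    tags = [f"LL{ll.shape[0]}x{ll.shape[1]}:{i}" for i in range(ll.size)]
    nlev = len(details)
    for d, (lh, hl, hh) in enumerate(details):
        lev = nlev - d  # coarsest level = highest index
        for name, block in (("LH", lh), ("HL", hl), ("HH", hh)):
            parts.append(block.ravel())
            tags.extend(f"{name}{lev}:{i}" for i in range(block.size))
    return np.concatenate(parts), tags


def padded_area(shape: Tuple[int, int], levels: int) -> int:
    """Element count of the coefficient vector for a plane of given shape."""
    ny, nx = shape
    total = 0
    for _ in range(levels):
        ny, nx = (ny + ny % 2), (nx + nx % 2)
        total += 3 * (ny // 2) * (nx // 2)
        ny, nx = ny // 2, nx // 2
    return total + ny * nx


def collapse_z(patch: np.ndarray, weighting: ZWeighting) -> np.ndarray:
    """Gaussian-weighted sum over the z axis of a (nz, ny, nx) patch."""
    w = np.asarray(weighting.weights)
    if len(w) != patch.shape[0]:
        raise ArgumentError(
            f"weighting covers {len(w)} slices, patch has {patch.shape[0]}")
    return np.tensordot(w, patch, axes=(0, 0))


def features_aniso_wavelet_3d(volume: ImageVolume, center: Coordinate,
                              geometry: PatchGeometry,
                              spec: WaveletSpec = WaveletSpec(),
                              weighting: ZWeighting | None = None
                              ) -> Tuple[np.ndarray, List[str]]:
    """Anisotropic wavelet feature vector for one voxel of interest.

    Extracts the patch around ``center``, collapses z with the Gaussian
    weights, and returns all multi-level 2D Haar coefficients of the
    resulting plane, flattened in the documented order.  Vector length is
    the padded patch area, independent of rz.
    """
    if weighting is None:
        weighting = gaussian_z_weights(geometry.rz)
    patch = extract_patch(volume, center, geometry)
    plane = collapse_z(patch, weighting)
    ll, details = haar_decompose(plane, spec.levels)
    values, tags = flatten_coefficients(ll, details)
    return values, [f"aniso3d/{t}" for t in tags]


def features_haar_2d(image: ImageVolume, spec: WaveletSpec = WaveletSpec(),
                     pooling: str = "subband-stats"
                     ) -> Tuple[np.ndarray, List[str]]:
    """2D Haar wavelet features of a single-slice image.

    pooling="raw-roi": the flattened coefficients (fixed-size ROI patches).
    pooling="subband-stats": per subband per level, mean and standard
    deviation of absolute coefficients -> length 2*(3*levels + 1); suited to
    whole images of varying size.
    """
    if not image.is_2d:
        raise ArgumentError("features_haar_2d requires a 2D image (nz == 1)")
    ll, details = haar_decompose(image.plane(0), spec.levels)
    if pooling == "raw-roi":
        values, tags = flatten_coefficients(ll, details)
        return values, [f"haar2d/{t}" for t in tags]
    if pooling != "subband-stats":
        raise ConfigurationError(
            f"unknown pooling {pooling!r}; use 'raw-roi' or 'subband-stats'")
    values: List[float] = []
    tags: List[str] = []
    nlev = len(details)

    def stats(block: np.ndarray, name: str) -> None:
        a = np.abs(block)
        values.extend([float(a.mean()), float(a.std())])
        tags.extend([f"haar2d/{name}:mean", f"haar2d/{name}:std"])

    stats(ll, f"LL{nlev}")
    for d, (lh, hl, hh) in enumerate(details):
        lev = nlev - d
        stats(lh, f"LH{lev}")
        stats(hl, f"HL{lev}")
        stats(hh, f"HH{lev}")
    return np.asarray(values), tags
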