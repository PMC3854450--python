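"""Deterministic synthetic fixtures for every pipeline stage.

Three generators emulate the image classes the pipeline is designed for:

* blob volumes: anisotropic Gaussian blobs on a noisy dark background with
  known centres, standing in for confocal stacks of fluorescently labelled
  cell nuclei (z spread smaller than x-y spread, crowded bright objects);
* two-class texture sets: low- versus high-frequency sinusoid-modulated
  noise images, a stand-in for texture-discriminable whole-image sets;
* tube images: a bright smooth ridge, the minimal axon-like structure for
  Hessian-feature checks.

All generators are pure functions of their spec (identical seed gives a
bit-identical result) and write the same on-disk formats the IO layer
reads, so tests exercise the real file paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
import tifffile

from .errors import GenerationError
from .io import LabeledImageSet, load_labeled_set
from .vaa3d import write_vaa3d_marker
from .volume import Coordinate, ImageVolume
from .wavelets import WaveletSpec, features_haar_2d


@dataclass(frozen=True)
class BlobVolumeSpec:
    """Anisotropic Gaussian blobs + clipped Gaussian background noise.

    Defaults model a small nucleus-counting stack: 20 blobs of x-y spread
    2.5 voxels and z spread 1.5 (axial resolution coarser than lateral),
    peak 200 over a noise floor of sigma 5, at least 12 voxels between
    centres so neighbouring nuclei stay resolvable (>= 4 sigma).
    """

    nx: int = 64
    ny: int = 64
    nz: int = 24
    n_blobs: int = 20
    sigma: float = 2.5
    z_sigma: float = 1.5
    peak: float = 200.0
    noise_sigma: float = 5.0
    min_separation: float = 12.0
    seed: int = 0


@dataclass(frozen=True)
class TextureSetSpec:
    """Two-class sinusoid-texture set written as a directory tree.

    The "easy" preset separates the classes by an order of magnitude in
    carrier frequency (2 vs 16 cycles per image) at low noise, with one
    fixed grating per class (orientation and phase drawn once from the
    seed) so the only intra-class variation is pixel noise; that is what
    guarantees the inter-class feature distance exceeding 10x the
    intra-class spread.  "hard" brings the frequencies closer, randomises
    orientation and phase per image and raises the noise.
    """

    images_per_class: int = 10
    size: int = 32
    preset: str = "easy"
    seed: int = 0

    def frequencies(self) -> Tuple[float, float]:
        return (2.0, 16.0) if self.preset == "easy" else (6.0, 9.0)

    def noise_sigma(self) -> float:
        return 0.02 if self.preset == "easy" else 0.25


def gen_blob_volume(spec: BlobVolumeSpec
                    ) -> Tuple[ImageVolume, List[Coordinate]]:
    """Blob volume plus exact ground-truth centres."""
    rng = np.random.default_rng(spec.seed)
    margin = int(np.ceil(3 * spec.sigma))
    zmargin = int(np.ceil(2 * spec.z_sigma))
    if spec.nx - 2 * margin <= 0 or spec.ny - 2 * margin <= 0 \
            or spec.nz - 2 * zmargin <= 0:
        raise GenerationError("volume too small for the blob spread")
    centers: List[Tuple[int, int, int]] = []
    attempts = 0
    while len(centers) < spec.n_blobs:
        attempts += 1
        if attempts > 2000 * spec.n_blobs:
            raise GenerationError(
                f"cannot place {spec.n_blobs} blobs with separation "
                f">= {spec.min_separation} in "
                f"{spec.nx}x{spec.ny}x{spec.nz}")
        c = (int(rng.integers(margin, spec.nx - margin)),
             int(rng.integers(margin, spec.ny - margin)),
             int(rng.integers(zmargin, spec.nz - zmargin)))
        if all(np.linalg.norm(np.subtract(c, o)) >= spec.min_separation
               for o in centers):
            centers.append(c)
    zs, ys, xs = np.mgrid[0:spec.nz, 0:spec.ny, 0:spec.nx].astype(float)
    data = np.zeros((spec.nz, spec.ny, spec.nx))
    for cx, cy, cz in centers:
        data += spec.peak * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * spec.sigma ** 2)
            - (zs - cz) ** 2 / (2 * spec.z_sigma ** 2))
    data += np.abs(rng.normal(0.0, spec.noise_sigma, data.shape))
    volume = ImageVolume(data)
    return volume, [Coordinate(x, y, z) for x, y, z in centers]


def _texture_image(rng: np.random.Generator, size: int, freq: float,
                   noise_sigma: float, theta: float | None = None,
                   phase: float | None = None) -> np.ndarray:
    if theta is None:
        theta = rng.uniform(0, np.pi)
    if phase is None:
        phase = rng.uniform(0, 2 * np.pi)
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    u = (xs * np.cos(theta) + ys * np.sin(theta)) / size
    img = 0.5 + 0.5 * np.sin(2 * np.pi * freq * u + phase)
    img += rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def _haar_stat_features(data: np.ndarray) -> np.ndarray:
    values, _ = features_haar_2d(ImageVolume(data), WaveletSpec(2),
                                 pooling="subband-stats")
    return values


def gen_texture_set(spec: TextureSetSpec, out_dir: str | Path
                    ) -> LabeledImageSet:
    """Write the two-class texture tree and return it loaded through IO.

    For the "easy" preset the separation guarantee is asserted at
    generation time: the distance between class feature centroids (Haar
    subband statistics) must exceed 10x the largest intra-class spread.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    f_low, f_high = spec.frequencies()
    feats = {0: [], 1: []}
    for cls, freq in ((0, f_low), (1, f_high)):
        cls_dir = out_dir / f"class{cls}"
        cls_dir.mkdir(parents=True, exist_ok=True)
        if spec.preset == "easy":
            # one fixed grating per class; noise is the only variation
            theta, phase = 0.0, float(rng.uniform(0, 2 * np.pi))
        else:
            theta = phase = None
        for i in range(spec.images_per_class):
            img = _texture_image(rng, spec.size, freq, spec.noise_sigma(),
                                 theta=theta, phase=phase)
            tifffile.imwrite(cls_dir / f"tex{i:03d}.tif", img)
            feats[cls].append(_haar_stat_features(img.astype(float)))
    if spec.preset == "easy":
        c0 = np.mean(feats[0], axis=0)
        c1 = np.mean(feats[1], axis=0)
        inter = np.linalg.norm(c0 - c1)
        intra = max(
            float(np.mean([np.linalg.norm(f - c0) for f in feats[0]])),
            float(np.mean([np.linalg.norm(f - c1) for f in feats[1]])))
        if inter <= 10 * intra:
            raise GenerationError(
                f"easy preset failed its separation guarantee "
                f"(inter={inter:.3g}, intra={intra:.3g})")
    return load_labeled_set("directory-tree", out_dir)


def gen_tube_image(size: int = 64, width: float = 3.0,
                   orientation_deg: float = 0.0, seed: int = 0,
                   noise_sigma: float = 0.0) -> ImageVolume:
    """A bright smooth ridge through the image centre at the given
    orientation (0 deg = horizontal tube along x)."""
    if width >= size / 4:
        raise GenerationError("tube width must be < size/4")
    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    cx = cy = (size - 1) / 2.0
    theta = np.deg2rad(orientation_deg)
    # signed distance to the centre line with direction (cos, sin)
    d = -(xs - cx) * np.sin(theta) + (ys - cy) * np.cos(theta)
    img = np.exp(-d ** 2 / (2 * width ** 2)) * 100.0
    if noise_sigma > 0:
        img = img + np.abs(rng.normal(0.0, noise_sigma, img.shape))
    return ImageVolume(img)


def sample_background_points(volume: ImageVolume,
                             centers: List[Coordinate], n: int,
                             min_distance: float, seed: int,
                             margin: int = 3) -> List[Coordinate]:
    """Random coordinates at least ``min_distance`` from every centre."""
    rng = np.random.default_rng(seed)
    pts: List[Coordinate] = []
    ctr = np.array([c.as_tuple() for c in centers], dtype=float)
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise GenerationError("cannot place background points")
        p = np.array([rng.integers(margin, volume.nx - margin),
                      rng.integers(margin, volume.ny - margin),
                      rng.integers(0, volume.nz)], dtype=float)
        if np.min(np.linalg.norm(ctr - p, axis=1)) >= min_distance:
            pts.append(Coordinate(int(p[0]), int(p[1]), int(p[2])))
    return pts


def write_demo_workspace(out_dir: str | Path, seed: int = 0) -> Path:
    """A complete demo workspace on disk.

    Contents: a training blob volume with positive (centre) and negative
    (background) marker files, a test blob volume with its ground-truth
    centres, and an easy two-class texture tree.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_spec = BlobVolumeSpec(seed=seed)
    test_spec = BlobVolumeSpec(seed=seed + 1)
    for tag, spec in (("train", train_spec), ("test", test_spec)):
        vol, centers = gen_blob_volume(spec)
        d = out_dir / tag
        d.mkdir(exist_ok=True)
        tifffile.imwrite(d / "volume.tif",
                         vol.data.astype(np.float32))
        write_vaa3d_marker(d / "pos.marker", centers)
        if tag == "train":
            neg = sample_background_points(
                vol, centers, n=len(centers), min_distance=8.0,
                seed=seed + 100)
            write_vaa3d_marker(d / "neg.marker", neg)
    gen_texture_set(TextureSetSpec(seed=seed), out_dir / "textures")
    return out_dir
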