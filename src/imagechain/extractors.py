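"""Configurable feature extractors with a uniform interface.

Every extractor maps an ImageVolume (a whole image, or an ROI patch wrapped
as a volume) to a FeatureVector whose length depends only on the
extractor's configuration, never on image content.  Extractors are
addressed by name in chain configurations; parameters are keyword fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .differential import differential_features
from .errors import ConfigurationError
from .features import FeatureVector
from .moments import hu_moments_2d, hu_moments_3d, zernike_moments
from .objects import object_statistics, object_territory, segment_objects
from .volume import Coordinate, ImageVolume
from .wavelets import (WaveletSpec, collapse_z, features_haar_2d,
                       flatten_coefficients, gaussian_z_weights,
                       haar_decompose)


class Extractor:
    """Base extractor: subclasses implement extract(volume)."""

    name: str = "extractor"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.name}>"


@dataclass
class Haar2DExtractor(Extractor):
    """2D Haar wavelet features of the (z-flattened) image."""

    levels: int = 2
    pooling: str = "subband-stats"
    name: str = "haar2d"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        if not volume.is_2d:
            # flatten a stack by its central slice for 2D texture features
            volume = ImageVolume(volume.data[volume.nz // 2])
        values, tags = features_haar_2d(volume, WaveletSpec(self.levels),
                                        pooling=self.pooling)
        return FeatureVector(values, tags)


@dataclass
class AnisoWavelet3DExtractor(Extractor):
    """3D anisotropic wavelet: Gaussian z-collapse then 2D Haar transform.

    Applied to an ROI patch (or a whole stack): the Gaussian slice weights
    are centred on the middle slice; sigma defaults to max(rz, 1)/2.
    """

    levels: int = 2
    sigma: Optional[float] = None
    name: str = "aniso-wavelet-3d"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        rz = (volume.nz - 1) // 2
        weighting = gaussian_z_weights(rz, self.sigma)
        plane = collapse_z(volume.data, weighting)
        ll, details = haar_decompose(plane, self.levels)
        values, tags = flatten_coefficients(ll, details)
        return FeatureVector(values, [f"aniso3d/{t}" for t in tags])


@dataclass
class Hu2DExtractor(Extractor):
    name: str = "hu2d"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        plane = volume.plane(volume.nz // 2) if not volume.is_2d \
            else volume.plane(0)
        values = hu_moments_2d(plane)
        return FeatureVector(values, [f"hu2d/{i + 1}" for i in range(8)])


@dataclass
class Hu3DExtractor(Extractor):
    name: str = "hu3d"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        values = hu_moments_3d(volume)
        tags = ["hu3d/J1", "hu3d/J2", "hu3d/J3"] + \
            [f"hu3d/b{i}" for i in range(1, 6)]
        return FeatureVector(values, tags)


@dataclass
class ZernikeExtractor(Extractor):
    count: int = 20
    name: str = "zernike"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        plane = volume.plane(volume.nz // 2)
        values = zernike_moments(plane, self.count)
        return FeatureVector(values,
                             [f"zernike/{i}" for i in range(self.count)])


@dataclass
class ObjectStatsExtractor(Extractor):
    threshold: object = "otsu"  # "otsu" or a fixed number
    name: str = "object-stats"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        objects = segment_objects(volume, self.threshold)
        values = object_statistics(objects)
        tags = ["objstat/count", "objstat/size-mean", "objstat/size-var",
                "objstat/dist-mean", "objstat/dist-var",
                "objstat/size-ratio", "objstat/dist-ratio"]
        return FeatureVector(values, tags)


@dataclass
class TerritoryExtractor(Extractor):
    threshold: object = "otsu"
    name: str = "territory"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        objects = segment_objects(volume, self.threshold)
        return FeatureVector(object_territory(objects), ["territory/total"])


@dataclass
class DifferentialExtractor(Extractor):
    scales: Tuple[float, ...] = (1.0, 2.0)
    pooling: str = "image-stats"
    name: str = "differential"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        values, tags = differential_features(volume, self.scales,
                                             pooling=self.pooling)
        return FeatureVector(values, tags)


@dataclass
class MeanIntensityExtractor(Extractor):
    """Single mean-intensity feature; mostly useful as a plugin example."""

    name: str = "mean-intensity"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        return FeatureVector(np.array([volume.data.mean()]),
                             ["mean-intensity/mean"])


@dataclass
class ConstantExtractor(Extractor):
    """Emits a constant; a deliberately uninformative baseline."""

    value: float = 1.0
    length: int = 1
    name: str = "constant"

    def extract(self, volume: ImageVolume) -> FeatureVector:
        return FeatureVector(np.full(self.length, self.value),
                             [f"constant/{i}" for i in range(self.length)])


BUILTIN_EXTRACTORS: Dict[str, Callable[..., Extractor]] = {
    "haar2d": Haar2DExtractor,
    "aniso-wavelet-3d": AnisoWavelet3DExtractor,
    "hu2d": Hu2DExtractor,
    "hu3d": Hu3DExtractor,
    "zernike": ZernikeExtractor,
    "object-stats": ObjectStatsExtractor,
    "territory": TerritoryExtractor,
    "differential": DifferentialExtractor,
    "mean-intensity": MeanIntensityExtractor,
    "constant": ConstantExtractor,
}


def make_extractor(name: str, **params) -> Extractor:
    if name not in BUILTIN_EXTRACTORS:
        raise ConfigurationError(
            f"unknown extractor {name!r}; built-ins: "
            f"{sorted(BUILTIN_EXTRACTORS)}")
    try:
        return BUILTIN_EXTRACTORS[name](**params)
    except TypeError as exc:
        raise ConfigurationError(f"extractor {name!r}: {exc}")
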