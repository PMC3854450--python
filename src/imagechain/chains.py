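"""Algorithm chains: aggregation, repeated-CV evaluation, ranking,
training and persistence.

A chain is an ordered list of feature extractors, an optional cascade of
feature selectors, and exactly one classifier.  Chains are the unit of
model selection: each candidate chain is evaluated by repeated stratified
k-fold cross-validation (default 5 folds x 5 repeats = 25 runs, the
reshuffling seeded per repeat), and candidates are ranked by mean accuracy.
All chains under one comparison see identical fold assignments so the
comparison is paired.

Selectors are fitted inside each training fold only, never on the full
set, so feature selection cannot leak held-out information.
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, TrainedClassifier, fit_classifier, \
    predict
from .errors import ArgumentError, ContractError, DataError, FormatError
from .extractors import Extractor
from .features import FeatureMatrix, FeatureVector
from .io import LabeledImageSet, ROISet
from .selection import SelectorSpec, cascade_select
from .volume import Coordinate, ImageVolume, PatchGeometry, extract_patch, \
    patch_as_volume

MODEL_FORMAT = "imagechain-model"
MODEL_VERSION = 1


@dataclass
class AlgorithmChain:
    name: str
    extractors: List[Extractor]
    selectors: List[SelectorSpec] = field(default_factory=list)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)

    def __post_init__(self) -> None:
        if not self.extractors:
            raise ArgumentError(f"chain {self.name!r} needs >= 1 extractor")


@dataclass(frozen=True)
class EvaluationProtocol:
    folds: int = 5
    repeats: int = 5
    stratified: bool = True
    seed: int = 0
    mode: str = "cross-validation"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ArgumentError("folds must be >= 2")
        if self.repeats < 1:
            raise ArgumentError("repeats must be >= 1")

    @property
    def total_runs(self) -> int:
        return self.folds * self.repeats


@dataclass
class ChainResult:
    chain_name: str
    accuracies: List[float]
    n_features_total: int
    n_features_selected: int
    fold_hashes: List[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def variance(self) -> float:
        # population variance over the runs (N, not N-1)
        return float(np.var(self.accuracies))

    def to_dict(self) -> Dict:
        return {
            "chain": self.chain_name,
            "accuracies": [float(a) for a in self.accuracies],
            "mean_accuracy": self.mean_accuracy,
            "variance": self.variance,
            "n_features_total": self.n_features_total,
            "n_features_selected": self.n_features_selected,
        }


def _extract_all(extractors: Sequence[Extractor],
                 volume: ImageVolume, ref: str
                 ) -> Tuple[np.ndarray, List[str]]:
    values: List[np.ndarray] = []
    tags: List[str] = []
    for ext in extractors:
        try:
            fv = ext.extract(volume)
        except Exception as exc:
            raise DataError(
                f"extractor {ext.name!r} failed on sample {ref!r}: {exc}")
        values.append(fv.values)
        tags.extend(fv.provenance)
    return np.concatenate(values), tags


def featurize_set(extractors: Sequence[Extractor],
                  samples: Union[LabeledImageSet, ROISet]
                  ) -> FeatureMatrix:
    """Aggregate all extractors over all samples (row per sample).

    Columns are the concatenation of each extractor's vector in extractor
    order (combined dimensionality = sum of the individual lengths).
    Samples are visited sequentially, one image resident at a time; in ROI
    mode the image is read once and patches are cut per labelled point.
    """
    rows: List[np.ndarray] = []
    labels: List[str] = []
    ids: List[str] = []
    tags: Optional[List[str]] = None
    if isinstance(samples, ROISet):
        volume = samples.load_image()
        samples.validate_bounds(volume)
        for c, lbl in samples.points:
            patch = extract_patch(volume, c, samples.geometry)
            vec, t = _extract_all(extractors, patch_as_volume(patch),
                                  f"{samples.image_path}@{c.as_tuple()}")
            rows.append(vec)
            labels.append(lbl)
            ids.append(f"{c.x},{c.y},{c.z}")
            tags = t if tags is None else tags
    else:
        if not samples.single_label:
            raise ArgumentError(
                "featurize_set needs single-label entries; decompose "
                "multi-label tasks into binary problems first")
        for ref, label_set in samples.entries:
            volume = samples.load_image(ref)
            vec, t = _extract_all(extractors, volume, ref)
            rows.append(vec)
            labels.append(next(iter(label_set)))
            ids.append(ref)
            tags = t if tags is None else tags
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ContractError(
            f"extractors produced varying feature lengths across samples "
            f"({sorted(lengths)}); lengths must depend only on "
            "configuration")
    matrix = np.vstack(rows)
    return FeatureMatrix(matrix, tags, labels=labels, row_ids=ids)


def fold_assignments(labels: Sequence[str], protocol: EvaluationProtocol
                     ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) pairs for folds x repeats runs.

    Each repeat reshuffles with a seed derived from the protocol seed, so a
    fixed protocol yields identical partitions for every chain (paired
    comparison).  Folds are stratified; if the smallest class has fewer
    members than ``folds``, the fold count is clamped with a warning.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ArgumentError("evaluation requires >= 2 classes")
    folds = protocol.folds
    if counts.min() < folds:
        warnings.warn(
            f"smallest class has {counts.min()} members; "
            f"folds clamped from {folds} to {max(int(counts.min()), 2)}")
        folds = max(int(counts.min()), 2)
    runs: List[Tuple[np.ndarray, np.ndarray]] = []
    for rep in range(protocol.repeats):
        rs = int(np.random.SeedSequence([protocol.seed, rep])
                 .generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            runs.append((train_idx, test_idx))
    return runs


def _fold_hash(test_idx: np.ndarray) -> str:
    payload = ",".join(map(str, sorted(int(i) for i in test_idx)))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def evaluate_features(matrix: FeatureMatrix, chain: AlgorithmChain,
                      protocol: EvaluationProtocol) -> ChainResult:
    """Repeated stratified CV on a precomputed feature matrix.

    Per run: selectors (if any) are fitted on the training rows only, the
    classifier is fitted on the selected training columns, and accuracy is
    scored on the held-out rows.
    """
    if matrix.labels is None:
        raise ArgumentError("evaluation requires labelled rows")
    runs = fold_assignments(matrix.labels, protocol)
    accuracies: List[float] = []
    hashes: List[str] = []
    n_selected = matrix.n_features
    for train_idx, test_idx in runs:
        train = matrix.subset_rows(train_idx)
        test = matrix.subset_rows(test_idx)
        test_labels = [matrix.labels[i] for i in test_idx]
        if chain.selectors:
            train_sel, kept = cascade_select(train, chain.selectors)
            test_sel = test.subset_columns(kept)
            n_selected = len(kept)
        else:
            train_sel, test_sel = train, test
        model = fit_classifier(chain.classifier, train_sel)
        pred = predict(model, test_sel)
        accuracies.append(
            float(np.mean([p == t for p, t in zip(pred, test_labels)])))
        hashes.append(_fold_hash(test_idx))
    return ChainResult(chain_name=chain.name, accuracies=accuracies,
                       n_features_total=matrix.n_features,
                       n_features_selected=n_selected,
                       fold_hashes=hashes)


def evaluate_chain(chain: AlgorithmChain,
                   samples: Union[LabeledImageSet, ROISet],
                   protocol: EvaluationProtocol) -> ChainResult:
    matrix = featurize_set(chain.extractors, samples)
    return evaluate_features(matrix, chain, protocol)


def compare_chains(chains: Sequence[AlgorithmChain],
                   samples: Union[LabeledImageSet, ROISet],
                   protocol: EvaluationProtocol
                   ) -> Tuple[List[ChainResult], ChainResult]:
    """Evaluate every chain under identical fold assignments and rank them.

    Ranking: mean accuracy descending; ties prefer fewer selected features
    (compact models), then earlier chain order.  Returns the ordered
    results and the winner.
    """
    if not chains:
        raise ArgumentError("compare_chains requires >= 1 chain")
    results = [evaluate_chain(chain, samples, protocol) for chain in chains]
    hashes = {tuple(r.fold_hashes) for r in results}
    if len(hashes) != 1:  # pragma: no cover - guarded by shared protocol
        raise ContractError("chains saw different fold assignments")
    order = sorted(range(len(results)),
                   key=lambda i: (-results[i].mean_accuracy,
                                  results[i].n_features_selected, i))
    ranked = [results[i] for i in order]
    return ranked, ranked[0]


@dataclass
class TrainedModel:
    """A chain fitted on a full training set, ready for prediction."""

    chain: AlgorithmChain
    classifier: TrainedClassifier
    selected_columns: List[int]
    column_names: List[str]
    classes: List[str]
    geometry: Optional[PatchGeometry] = None
    format_version: int = MODEL_VERSION

    def _featurize_volumes(self, volumes: Sequence[ImageVolume]
                           ) -> FeatureMatrix:
        rows = []
        tags: Optional[List[str]] = None
        for i, vol in enumerate(volumes):
            vec, t = _extract_all(self.chain.extractors, vol, f"probe-{i}")
            rows.append(vec)
            tags = t if tags is None else tags
        matrix = FeatureMatrix(np.vstack(rows), tags)
        return matrix.subset_columns(self.selected_columns)

    def predict_volumes(self, volumes: Sequence[ImageVolume]) -> List[str]:
        return predict(self.classifier, self._featurize_volumes(volumes))

    def predict_patch(self, volume: ImageVolume, center: Coordinate,
                      geometry: PatchGeometry) -> str:
        if self.geometry is not None and geometry != self.geometry:
            raise ContractError(
                f"model was trained with patch geometry {self.geometry}, "
                f"annotation requested {geometry}")
        patch = extract_patch(volume, center, geometry)
        return self.predict_volumes([patch_as_volume(patch)])[0]


def train_model(chain: AlgorithmChain,
                samples: Union[LabeledImageSet, ROISet]) -> TrainedModel:
    """Fit selectors and classifier on the full labelled set."""
    matrix = featurize_set(chain.extractors, samples)
    if chain.selectors:
        selected, kept = cascade_select(matrix, chain.selectors)
    else:
        selected, kept = matrix, list(range(matrix.n_features))
    classifier = fit_classifier(chain.classifier, selected)
    geometry = samples.geometry if isinstance(samples, ROISet) else None
    return TrainedModel(chain=chain, classifier=classifier,
                        selected_columns=kept,
                        column_names=list(matrix.columns),
                        classes=classifier.classes, geometry=geometry)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist to a single versioned archive file."""
    payload = {"format": MODEL_FORMAT, "version": model.format_version,
               "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError,
            MemoryError) as exc:
        raise FormatError(f"{path}: not a readable model archive: {exc}")
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not a model archive")
    if payload.get("version") != MODEL_VERSION:
        raise FormatError(
            f"{path}: model format version {payload.get('version')} "
            f"not supported (expected {MODEL_VERSION})")
    return payload["model"]
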