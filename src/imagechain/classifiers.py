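"""Uniform train/predict contract over the classifier inventory.

Kinds: knn (default k=3), svm-linear (regularisation C=1), naive-bayes,
decision-tree, random-forest (100 trees).  Defaults follow the platform's
stated settings: the nearest-neighbour classifier is a 3NN and the SVM uses
a linear kernel with C = 1.

kNN is implemented here because its tie-break is part of the contract: on a
vote tie, the label of the single nearest neighbour among the tied classes
wins.  The other kinds are backed by scikit-learn estimators behind this
module's contract (defaults, determinism under the seed, error cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ArgumentError, ConfigurationError, ContractError
from .features import FeatureMatrix

KINDS = ("knn", "svm-linear", "naive-bayes", "decision-tree", "random-forest")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "knn"
    k: int = 3
    C: float = 1.0
    n_trees: int = 100
    max_depth: Optional[int] = None
    seed: int = 0
    # optional per-column z-scaling fitted on the training rows; off by
    # default so distance-based kinds see raw feature units
    zscale: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(
                f"unknown classifier kind {self.kind!r}; one of {KINDS}")
        if self.k < 1 or self.C <= 0 or self.n_trees < 1:
            raise ArgumentError("invalid classifier hyperparameters")


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    classes: List[str]
    columns: List[str]
    _train_x: Optional[np.ndarray] = None      # knn only
    _train_y: Optional[np.ndarray] = None
    _estimator: object = None                  # sklearn-backed kinds
    _scale_mean: Optional[np.ndarray] = None   # zscale only
    _scale_std: Optional[np.ndarray] = None

    def predict(self, matrix: FeatureMatrix) -> List[str]:
        return predict(self, matrix)


def fit_classifier(spec: ClassifierSpec,
                   matrix: FeatureMatrix) -> TrainedClassifier:
    if matrix.labels is None:
        raise ArgumentError("training matrix must carry labels")
    labels = np.asarray([str(l) for l in matrix.labels])
    classes = sorted({str(l) for l in labels})
    if len(classes) < 2:
        raise ArgumentError("training requires at least 2 classes")
    if matrix.n_samples < len(classes):
        raise ArgumentError("fewer rows than classes")
    model = TrainedClassifier(spec=spec, classes=classes,
                              columns=list(matrix.columns))
    x = matrix.values
    if spec.zscale:
        model._scale_mean = x.mean(axis=0)
        model._scale_std = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        x = (x - model._scale_mean) / model._scale_std
    if spec.kind == "knn":
        model._train_x = x.copy()
        model._train_y = labels.copy()
        return model
    if spec.kind == "svm-linear":
        est = SVC(kernel="linear", C=spec.C, random_state=spec.seed)
    elif spec.kind == "naive-bayes":
        est = GaussianNB()
    elif spec.kind == "decision-tree":
        est = DecisionTreeClassifier(max_depth=spec.max_depth,
                                     random_state=spec.seed)
    elif spec.kind == "random-forest":
        est = RandomForestClassifier(n_estimators=spec.n_trees,
                                     max_depth=spec.max_depth,
                                     random_state=spec.seed)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ConfigurationError(f"unknown kind {spec.kind!r}")
    est.fit(x, labels)
    model._estimator = est
    return model


def _apply_scaling(model: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    if model._scale_mean is None:
        return x
    return (x - model._scale_mean) / model._scale_std


def _knn_predict(model: TrainedClassifier, x: np.ndarray) -> List[str]:
    k = min(model.spec.k, model._train_x.shape[0])
    d = cdist(x, model._train_x)  # Euclidean on unscaled features
    out: List[str] = []
    for row in d:
        order = np.argsort(row, kind="stable")[:k]
        votes: Dict[str, int] = {}
        for idx in order:
            votes[model._train_y[idx]] = votes.get(model._train_y[idx], 0) + 1
        top = max(votes.values())
        tied = {c for c, v in votes.items() if v == top}
        if len(tied) == 1:
            out.append(str(next(iter(tied))))
        else:
            # tie-break: label of the single nearest neighbour among
            # the tied classes
            for idx in order:
                if model._train_y[idx] in tied:
                    out.append(str(model._train_y[idx]))
                    break
    return out


def predict(model: TrainedClassifier, matrix: FeatureMatrix) -> List[str]:
    if list(matrix.columns) != model.columns:
        differing = [c for c in matrix.columns if c not in model.columns]
        missing = [c for c in model.columns if c not in matrix.columns]
        raise ContractError(
            "feature columns do not match the training matrix; "
            f"unexpected={differing[:5]}, missing={missing[:5]}")
    x = _apply_scaling(model, matrix.values)
    if model.spec.kind == "knn":
        return _knn_predict(model, x)
    return [str(lbl) for lbl in model._estimator.predict(x)]


def predict_scores(model: TrainedClassifier,
                   matrix: FeatureMatrix) -> Optional[np.ndarray]:
    """Per-class scores (n_samples, n_classes) for kinds that support them."""
    probe = _apply_scaling(model, matrix.values)
    if model.spec.kind == "knn":
        k = min(model.spec.k, model._train_x.shape[0])
        d = cdist(probe, model._train_x)
        scores = np.zeros((matrix.n_samples, len(model.classes)))
        for i, row in enumerate(d):
            order = np.argsort(row, kind="stable")[:k]
            for idx in order:
                scores[i, model.classes.index(model._train_y[idx])] += 1 / k
        return scores
    est = model._estimator
    if hasattr(est, "predict_proba"):
        try:
            proba = est.predict_proba(probe)
        except AttributeError:
            return None
        cols = [list(est.classes_).index(c) for c in model.classes]
        return proba[:, cols]
    return None
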