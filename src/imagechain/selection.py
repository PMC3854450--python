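"""Filter-style feature selection: Fisher-criterion scoring and cascades.

The Fisher score of column j is the proportion-weighted between-class
variance over the pooled within-class variance:

    score_j = sum_c p_c (mu_cj - mu_j)^2 / (sum_c p_c s2_cj + eps)

with p_c the class proportions, mu_cj the class means, mu_j the grand mean,
s2_cj the (population) class variances and eps = 1e-12 so that
zero-within-variance columns rank at the top instead of dividing by zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ArgumentError
from .features import FeatureMatrix

EPS = 1e-12


@dataclass(frozen=True)
class SelectorSpec:
    criterion: str = "fisher"
    n_keep: int = 500  # default: keep the best 500 features

    def __post_init__(self) -> None:
        if self.criterion != "fisher":
            raise ArgumentError(f"unknown criterion {self.criterion!r}")
        if self.n_keep < 1:
            raise ArgumentError("n_keep must be >= 1")


def fisher_scores(matrix: FeatureMatrix) -> np.ndarray:
    if matrix.labels is None:
        raise ArgumentError("fisher_scores requires labelled rows")
    labels = np.asarray(matrix.labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ArgumentError("fisher_scores requires at least 2 classes")
    x = matrix.values
    n = x.shape[0]
    grand = x.mean(axis=0)
    between = np.zeros(x.shape[1])
    within = np.zeros(x.shape[1])
    for c in classes:
        rows = x[labels == c]
        p = rows.shape[0] / n
        mu = rows.mean(axis=0)
        between += p * (mu - grand) ** 2
        within += p * rows.var(axis=0)
    return between / (within + EPS)


def select_features(matrix: FeatureMatrix, scores: Sequence[float],
                    n_keep: int) -> Tuple[FeatureMatrix, List[int]]:
    """Keep the n_keep highest-scoring columns, preserving original order.

    Ties break toward the lower original index; n_keep >= column count is
    the identity.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != matrix.n_features:
        raise ArgumentError("scores length must equal column count")
    if n_keep >= matrix.n_features:
        return matrix, list(range(matrix.n_features))
    # stable sort on -score keeps lower index first among ties
    order = np.argsort(-scores, kind="stable")[:n_keep]
    kept = sorted(int(i) for i in order)
    return matrix.subset_columns(kept), kept


def cascade_select(matrix: FeatureMatrix,
                   selectors: Sequence[SelectorSpec]
                   ) -> Tuple[FeatureMatrix, List[int]]:
    """Apply selectors sequentially, each re-scored on the previous output.

    Returns the reduced matrix and the mapping of surviving columns back to
    the original column indices.
    """
    if not selectors:
        raise ArgumentError("cascade requires at least one selector")
    current = matrix
    mapping = list(range(matrix.n_features))
    for spec in selectors:
        n_keep = spec.n_keep
        if n_keep > current.n_features:
            warnings.warn(
                f"selector n_keep={n_keep} exceeds surviving columns "
                f"({current.n_features}); clamped")
            n_keep = current.n_features
        scores = fisher_scores(current)
        current, kept = select_features(current, scores, n_keep)
        mapping = [mapping[i] for i in kept]
    return current, mapping
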