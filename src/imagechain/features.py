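"""Feature containers with provenance.

A FeatureMatrix is the rectangular sample-by-feature table produced by
aggregating extractor outputs; every column carries a provenance tag
(extractor name + per-index tag) so selected subsets remain traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import ArgumentError, ContractError


@dataclass
class FeatureVector:
    values: np.ndarray
    provenance: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.provenance):
            raise ContractError("provenance length must match value count")


@dataclass
class FeatureMatrix:
    """rows = samples, columns = features; optional per-row labels."""

    values: np.ndarray
    columns: List[str]
    labels: Optional[List[str]] = None
    row_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ArgumentError("feature matrix must be 2D")
        if self.values.shape[1] != len(self.columns):
            raise ArgumentError("column names must match column count")
        if len(set(self.columns)) != len(self.columns):
            raise ArgumentError("column provenance tags must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError("feature matrix contains non-finite values")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ArgumentError("labels must match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(self.values[:, idx],
                             [self.columns[i] for i in idx],
                             labels=self.labels, row_ids=self.row_ids)

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.values[idx, :], list(self.columns),
            labels=None if self.labels is None
            else [self.labels[i] for i in idx],
            row_ids=None if self.row_ids is None
            else [self.row_ids[i] for i in idx])
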