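"""Labelled feature datasets.

The classifier is a lazy learner: a :class:`FeatureDataset` holding the
training matrix *is* the fitted model. Features are opaque numeric vectors
(in the intended application, fixed-length embeddings of peptide
sequences); labels are small non-negative integers, ``0``/``1`` in the
binary case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, ContractViolationError

__all__ = ["FeatureDataset"]


@dataclass
class FeatureDataset:
    """An ``n x d`` feature matrix with per-row identifiers and labels.

    Parameters
    ----------
    ids
        Unique sample identifiers, one per row of ``X``.
    X
        Feature matrix, shape ``(n, d)``.
    y
        Integer class labels, shape ``(n,)``. A negative label marks an
        unlabelled row (used for prediction-only tables).
    metadata
        Free-form provenance (e.g. indices displaced by contamination).
    """

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.ids = [str(i) for i in self.ids]
        if self.X.ndim != 2:
            raise ContractViolationError("X must be a 2-D matrix")
        n = self.X.shape[0]
        if len(self.ids) != n or self.y.shape != (n,):
            raise ContractViolationError(
                f"inconsistent sizes: {len(self.ids)} ids, X has {n} rows, "
                f"y has shape {self.y.shape}"
            )
        if len(set(self.ids)) != n:
            raise ContractViolationError("sample ids must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted distinct non-negative labels."""
        c = np.unique(self.y)
        return c[c >= 0]

    def class_indices(self, c: int) -> np.ndarray:
        """Row indices of class ``c`` in ascending order."""
        return np.flatnonzero(self.y == c)

    def subset(self, indices: Sequence[int]) -> "FeatureDataset":
        idx = np.asarray(indices, dtype=int)
        return FeatureDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx].copy(),
            y=self.y[idx].copy(),
            metadata=dict(self.metadata),
        )

    def require_min_class_size(self, k: int) -> None:
        """Raise unless every class has at least ``k`` members."""
        for c in self.classes:
            m = int(np.sum(self.y == c))
            if m < k:
                raise ConfigurationError(
                    f"class {int(c)} has only {m} samples; at least {k} required"
                )
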