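"""Sparse binary label assignments and per-label confusion tallies.

A :class:`LabelMatrix` is the package's universal container: gold-standard
annotations and every component model's predictions are instances × labels
binary matrices over a shared document set and label vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LabelMatrix",
    "DatasetSplit",
    "ModelPredictions",
    "ConfusionCounts",
]


class LabelMatrix:
    """Binary instances × labels assignment stored as a sparse CSC matrix.

    Entries are strictly 0/1; duplicate coordinates collapse to a single
    positive entry at construction. Columns (labels) are the unit of work
    throughout the package, hence CSC storage.
    """

    __slots__ = ("_m",)

    def __init__(self, matrix) -> None:
        m = sp.csc_matrix(matrix, dtype=np.int8)
        m.sum_duplicates()
        if m.nnz:
            m.data[:] = 1
        m.eliminate_zeros()
        self._m = m

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[int, int]],
        n_instances: int,
        n_labels: int,
    ) -> "LabelMatrix":
        """Build from (instance-index, label-index) pairs.

        Indices must lie in ``[0, n_instances) × [0, n_labels)``; duplicates
        are tolerated and collapse to one entry.
        """
        pairs = list(pairs)
        if pairs:
            rows, cols = (np.asarray(x, dtype=np.int64) for x in zip(*pairs))
        else:
            rows = cols = np.empty(0, dtype=np.int64)
        if rows.size:
            if rows.min() < 0 or rows.max() >= n_instances:
                raise ValueError("instance index out of range")
            if cols.min() < 0 or cols.max() >= n_labels:
                raise ValueError("label index out of range")
        m = sp.coo_matrix(
            (np.ones(rows.size, dtype=np.int8), (rows, cols)),
            shape=(n_instances, n_labels),
        )
        return cls(m)

    @classmethod
    def from_dense(cls, array) -> "LabelMatrix":
        return cls(sp.csc_matrix(np.asarray(array) != 0, dtype=np.int8))

    # -- basic views -------------------------------------------------------

    @property
    def n_instances(self) -> int:
        return self._m.shape[0]

    @property
    def n_labels(self) -> int:
        return self._m.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._m.shape

    @property
    def nnz(self) -> int:
        return self._m.nnz

    def tocsc(self) -> sp.csc_matrix:
        return self._m

    def toarray(self) -> np.ndarray:
        return self._m.toarray()

    def positives(self) -> set[tuple[int, int]]:
        coo = self._m.tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))

    def column(self, label: int) -> np.ndarray:
        """Dense boolean indicator of the given label over all instances."""
        if not 0 <= label < self.n_labels:
            raise IndexError(f"label index {label} out of range")
        return (self._m[:, [label]].toarray().ravel() != 0)

    def column_indices(self, label: int) -> np.ndarray:
        """Row indices of positive instances for one label (sorted)."""
        if not 0 <= label < self.n_labels:
            raise IndexError(f"label index {label} out of range")
        m = self._m
        return m.indices[m.indptr[label] : m.indptr[label + 1]].copy()

    def label_counts(self) -> np.ndarray:
        """Number of positive instances per label."""
        return np.asarray(self._m.sum(axis=0)).ravel().astype(np.int64)

    def cardinalities(self) -> np.ndarray:
        """Number of labels per instance."""
        return np.asarray(self._m.sum(axis=1)).ravel().astype(np.int64)

    def with_columns_from(self, other: "LabelMatrix", labels: Sequence[int]) -> "LabelMatrix":
        """Copy with the listed label columns replaced by ``other``'s."""
        if other.shape != self.shape:
            raise ValueError("shape mismatch")
        out = self._m.tolil(copy=True)
        src = other._m
        for l in labels:
            out[:, l] = src[:, [l]]
        return LabelMatrix(out)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelMatrix):
            return NotImplemented
        if self.shape != other.shape:
            return False
        return (self._m != other._m).nnz == 0

    def __hash__(self):  # mutable-ish container; identity hash is fine
        return id(self)

    def __repr__(self) -> str:
        return (
            f"LabelMatrix({self.n_instances} instances × {self.n_labels} labels, "
            f"{self.nnz} positives)"
        )


@dataclass(frozen=True)
class DatasetSplit:
    """A named split (train/validation/test) with its gold assignment."""

    role: str
    gold: LabelMatrix

    _ROLES = ("train", "validation", "test")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class ModelPredictions:
    """One component model's binary predictions on a split."""

    model_id: str
    predictions: LabelMatrix

    def check_aligned(self, gold: LabelMatrix) -> None:
        if self.predictions.shape != gold.shape:
            raise ValueError(
                f"predictions of {self.model_id!r} have shape "
                f"{self.predictions.shape}, gold has {gold.shape}"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-label true-positive / false-positive / false-negative tallies.

    True negatives are implicit (derivable from the instance count); no
    evaluation measure used here needs them.
    """

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, arr)
        if not (self.tp.shape == self.fp.shape == self.fn.shape):
            raise ValueError("tp/fp/fn must have identical shapes")
        if (self.tp < 0).any() or (self.fp < 0).any() or (self.fn < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_labels(self) -> int:
        return self.tp.shape[0]

    def label(self, l: int) -> tuple[int, int, int]:
        return int(self.tp[l]), int(self.fp[l]), int(self.fn[l])

    def totals(self) -> tuple[int, int, int]:
        return int(self.tp.sum()), int(self.fp.sum()), int(self.fn.sum())
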