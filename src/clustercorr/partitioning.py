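"""Derive candidate clusterings (partitions) from a single variable.

The coefficient implemented by this package treats every variable as a
generator of partitions of the n observed objects.  A numerical variable is
cut at its empirical quantiles: for a requested cluster count ``k`` the
``k - 1`` interior quantiles (at fractions ``j/k``) define bins, and each
object is labelled by the bin its value falls into.  A categorical variable
contributes exactly one partition, in which the categories themselves are the
clusters; nominal labels are never ordered.

Boundary convention
-------------------
An object whose value equals a cutpoint is assigned to the *upper* bin
(left-closed bins).  Under heavy ties quantile cutpoints can coincide, which
collapses bins; empty bins are dropped and the remaining labels compacted.
A would-be partition with fewer than two non-empty clusters carries no
information and is discarded (``None``), not raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

NUMERICAL = "numerical"
CATEGORICAL = "categorical"

_KINDS = (NUMERICAL, CATEGORICAL)


@dataclass(frozen=True, eq=False)
class DataVector:
    """One variable observed over ``n`` objects.

    Parameters
    ----------
    values
        The observations: floats for a numerical variable, arbitrary
        hashable labels (strings, typically) for a categorical one.
    kind
        ``"numerical"`` or ``"categorical"``.
    """

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def is_constant(self) -> bool:
        """True when every (non-missing) observation takes the same value."""
        if self.kind == NUMERICAL:
            vals = self.values[~np.isnan(self.values)]
            return np.unique(vals).size <= 1
        return pd.unique(self.values[~pd.isna(self.values)]).size <= 1

    @classmethod
    def from_sequence(cls, values: Sequence, kind: Optional[str] = None) -> "DataVector":
        """Build a DataVector, inferring the kind from the dtype if not given.

        Numeric (float/int/bool) content is treated as numerical unless
        explicitly declared categorical; anything else is categorical.
        """
        arr = np.asarray(values)
        if kind is None:
            kind = NUMERICAL if arr.dtype.kind in "fiub" else CATEGORICAL
        if kind == NUMERICAL:
            arr = np.asarray(values, dtype=np.float64)
        else:
            arr = np.asarray(values, dtype=object)
        return cls(values=arr, kind=kind)


def as_data_vector(x: Union[DataVector, Sequence], kind: Optional[str] = None) -> DataVector:
    """Coerce raw sequences to :class:`DataVector`; pass DataVectors through."""
    if isinstance(x, DataVector):
        return x
    return DataVector.from_sequence(x, kind=kind)


@dataclass(frozen=True, eq=False)
class Partition:
    """An assignment of n objects into ``k >= 2`` non-empty clusters.

    ``labels`` holds a 0-based cluster index per object; every index in
    ``[0, k)`` occurs at least once.  ``source_k`` records the requested
    cluster count (which may exceed ``k`` when quantile ties collapsed bins)
    or the category count for categorical variables.
    """

    labels: np.ndarray
    k: int
    source_k: int

    @property
    def n(self) -> int:
        return int(self.labels.shape[0])


@dataclass(frozen=True, eq=False)
class PartitionSet:
    """All valid candidate partitions derived from one variable."""

    partitions: tuple
    variable_kind: str

    def __len__(self) -> int:
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    def __bool__(self) -> bool:
        return bool(self.partitions)


def quantile_cutpoints(values: Sequence[float], k: int) -> np.ndarray:
    """Interior quantile cutpoints at fractions j/k, j = 1..k-1.

    Uses rank-based linear interpolation (the conventional quantile
    estimator).  The returned array is non-decreasing; under heavy ties
    cutpoints may coincide.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot compute quantile cutpoints of an empty sequence")
    if k < 2:
        raise ValueError(f"cluster count k must be >= 2, got {k}")
    if np.isnan(arr).any():
        raise ValueError("values contain missing entries; drop or impute them first")
    fracs = np.arange(1, k) / k
    return np.quantile(arr, fracs, method="linear")


def partition_numeric(values: Sequence[float], k: int) -> Optional[Partition]:
    """Partition a numerical variable into (up to) k quantile bins.

    Each object's raw bin index is the number of cutpoints ``<=`` its value,
    so a value sitting exactly on a cutpoint goes to the upper bin.  Returns
    ``None`` when ties collapse everything into a single non-empty bin.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError(f"need at least 2 objects to partition, got {arr.size}")
    cut = quantile_cutpoints(arr, k)
    raw = np.searchsorted(cut, arr, side="right")
    nonempty, labels = np.unique(raw, return_inverse=True)
    if nonempty.size < 2:
        return None
    return Partition(labels=labels.astype(np.int64), k=int(nonempty.size), source_k=int(k))


def partition_categorical(values: Sequence) -> Optional[Partition]:
    """Partition a categorical variable: one cluster per distinct label.

    Cluster indices follow first appearance.  Returns ``None`` when fewer
    than two distinct categories are present.
    """
    arr = np.asarray(values, dtype=object)
    if arr.size == 0:
        raise ValueError("cannot partition an empty sequence")
    codes, uniques = pd.factorize(arr, use_na_sentinel=True)
    if (codes < 0).any():
        raise ValueError("categorical values contain missing entries")
    if len(uniques) < 2:
        return None
    return Partition(labels=codes.astype(np.int64), k=int(len(uniques)), source_k=int(len(uniques)))


def generate_partitions(v: DataVector, kmax: int = 10) -> PartitionSet:
    """All valid candidate partitions of one variable.

    Numerical variables yield at most ``kmax - 1`` partitions (one per
    requested cluster count in ``[2, kmax]``); duplicates arising from ties
    are dropped, keeping the lowest requested k.  Categorical variables yield
    the single category partition, independent of ``kmax``.  The result may
    be empty (e.g. ten identical values plus one outlier collapse every
    quantile split).
    """
    if kmax < 2:
        raise ValueError(f"kmax must be >= 2, got {kmax}")
    if v.n < 2:
        raise ValueError(f"need at least 2 objects, got {v.n}")
    if v.kind == CATEGORICAL:
        part = partition_categorical(v.values)
        parts = (part,) if part is not None else ()
        return PartitionSet(partitions=parts, variable_kind=CATEGORICAL)
    parts = []
    seen = set()
    for k in range(2, kmax + 1):
        part = partition_numeric(v.values, k)
        if part is None:
            continue
        key = part.labels.tobytes()
        if key in seen:
            continue
        seen.add(key)
        parts.append(part)
    return PartitionSet(partitions=tuple(parts), variable_kind=NUMERICAL)
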