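"""Adjusted Rand index via pair counting.

Two partitions of the same n objects classify each of the n(n-1)/2 object
pairs into four classes:

* ``n0`` — co-clustered in both partitions,
* ``n1`` — separated in both,
* ``n2`` — co-clustered in the first only,
* ``n3`` — co-clustered in the second only.

``n0 + n1`` pairs are agreements, ``n2 + n3`` disagreements, and

    ARI = 2 (n0 n1 - n2 n3) / [ (n0+n2)(n2+n1) + (n0+n3)(n3+n1) ]

which is 1 for identical partitions and concentrates at 0 for independently
drawn ones (the chance correction), irrespective of the cluster counts.

The counts are obtained from the k_p x k_q cluster-overlap contingency table
in O(n + k_p k_q); pairs are never enumerated.  Scalar results use exact
integer arithmetic.  The batched variant (used by the permutation test) works
in float64, exact for pair counts below 2^53 (n well beyond 10^8 objects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .partitioning import Partition

LabelsLike = Union[Partition, np.ndarray, "list[int]"]


@dataclass(frozen=True)
class PairCounts:
    n0: int
    n1: int
    n2: int
    n3: int

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2 + self.n3


def _as_labels(p: LabelsLike) -> Tuple[np.ndarray, int]:
    if isinstance(p, Partition):
        return p.labels, p.k
    arr = np.asarray(p)
    _, labels = np.unique(arr, return_inverse=True)
    k = int(labels.max()) + 1 if labels.size else 0
    return labels.astype(np.int64), k


def contingency_table(p: LabelsLike, q: LabelsLike) -> np.ndarray:
    """k_p x k_q table of cluster-overlap counts."""
    pl, kp = _as_labels(p)
    ql, kq = _as_labels(q)
    if pl.shape != ql.shape:
        raise ValueError(f"partitions cover different object counts: {pl.size} vs {ql.size}")
    return np.bincount(pl * kq + ql, minlength=kp * kq).reshape(kp, kq)


def pair_counts(p: LabelsLike, q: LabelsLike) -> PairCounts:
    """The four pair-agreement counts between two partitions."""
    cont = contingency_table(p, q).astype(np.int64)
    n = int(cont.sum())
    n0 = int((cont * (cont - 1) // 2).sum())
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    same_p = int((a * (a - 1) // 2).sum())  # n0 + n2
    same_q = int((b * (b - 1) // 2).sum())  # n0 + n3
    total = n * (n - 1) // 2
    n2 = same_p - n0
    n3 = same_q - n0
    n1 = total - n0 - n2 - n3
    return PairCounts(n0=n0, n1=n1, n2=n2, n3=n3)


def ari(p: LabelsLike, q: LabelsLike) -> float:
    """Adjusted Rand index between two partitions of the same objects.

    The degenerate denominator (both partitions all-singletons, or both a
    single cluster) is resolved by convention: 1 when the partitions are
    identical, 0 otherwise.
    """
    pc = pair_counts(p, q)
    num = 2 * (pc.n0 * pc.n1 - pc.n2 * pc.n3)
    den = (pc.n0 + pc.n2) * (pc.n2 + pc.n1) + (pc.n0 + pc.n3) * (pc.n3 + pc.n1)
    if den == 0:
        return 1.0 if (pc.n2 == 0 and pc.n3 == 0) else 0.0
    return num / den


def _ari_from_labels(pl: np.ndarray, kp: int, ql: np.ndarray, kq: int) -> float:
    """ARI for pre-compacted label arrays (hot path, no validation)."""
    cont = np.bincount(pl * kq + ql, minlength=kp * kq).astype(np.int64)
    n = pl.size
    n0 = int((cont * (cont - 1) // 2).sum())
    cont = cont.reshape(kp, kq)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    same_p = int((a * (a - 1) // 2).sum())
    same_q = int((b * (b - 1) // 2).sum())
    total = n * (n - 1) // 2
    n2 = same_p - n0
    n3 = same_q - n0
    n1 = total - n0 - n2 - n3
    num = 2 * (n0 * n1 - n2 * n3)
    den = (n0 + n2) * (n2 + n1) + (n0 + n3) * (n3 + n1)
    if den == 0:
        return 1.0 if (n2 == 0 and n3 == 0) else 0.0
    return num / den


def _ari_batch(x_labels: np.ndarray, kx: int, Y: np.ndarray, ky: int) -> np.ndarray:
    """ARI between one fixed partition and a stack of partitions.

    ``Y`` has shape (P, n): P label vectors over the same n objects as
    ``x_labels``.  Returns P index values.  One bincount builds all P
    contingency tables at once; the arithmetic is float64.
    """
    P, n = Y.shape
    codes = Y.astype(np.int64) * kx + x_labels[np.newaxis, :]
    codes += (np.arange(P, dtype=np.int64) * (kx * ky))[:, np.newaxis]
    cont = np.bincount(codes.ravel(), minlength=P * kx * ky)
    cont = cont.reshape(P, ky, kx).astype(np.float64)
    n0 = (cont * (cont - 1.0) / 2.0).sum(axis=(1, 2))
    a = cont.sum(axis=2)
    b = cont.sum(axis=1)
    same_y = (a * (a - 1.0) / 2.0).sum(axis=1)
    same_x = (b * (b - 1.0) / 2.0).sum(axis=1)
    total = n * (n - 1) / 2.0
    n2 = same_y - n0
    n3 = same_x - n0
    n1 = total - n0 - n2 - n3
    num = 2.0 * (n0 * n1 - n2 * n3)
    den = (n0 + n2) * (n2 + n1) + (n0 + n3) * (n3 + n1)
    out = np.zeros(P)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    deg = ~ok
    if deg.any():
        out[deg] = np.where((n2[deg] == 0) & (n3[deg] == 0), 1.0, 0.0)
    return out
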