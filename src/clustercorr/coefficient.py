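"""The clustering-based correlation coefficient (CCC) for variable pairs and matrices.

For two variables x and y over the same n objects, each variable is turned
into a set of candidate partitions (quantile bins for numerical variables at
every cluster count in [2, kmax]; the categories themselves for categorical
variables).  The coefficient is the maximum adjusted Rand index over the
Cartesian product of the two partition sets, clamped below at zero:

    CCC(x, y) = max(0, max_{pi in Px, pj in Py} ARI(pi, pj))  in [0, 1]

``kmax`` (default 10) is the single tuning parameter: it bounds the
complexity of detectable patterns (2 clusters suffice for monotone
relationships; quadratic or mixture patterns need more) and the cost, which
grows quadratically with it.  Thanks to the chance correction of the ARI,
independent variables score near zero for any ``kmax``.

A constant variable admits no partition and the coefficient is undefined
(NaN, with a logged warning).  A non-constant variable whose quantile splits
all collapse under ties (e.g. ten identical values plus one outlier) yields
an empty candidate set and a coefficient of exactly 0: detectable structure
is absent, but the comparison is well posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .ari import _ari_from_labels
from .partitioning import (
    CATEGORICAL,
    NUMERICAL,
    DataVector,
    Partition,
    PartitionSet,
    as_data_vector,
    generate_partitions,
)

logger = logging.getLogger("clustercorr")


@dataclass(frozen=True)
class CCCConfig:
    """Computation settings.

    kmax
        Maximum clusters per candidate partition (>= 2).  The default, 10,
        captures both linear and moderately complex patterns at modest cost.
    jobs
        Worker count for the pairwise-matrix driver (and for splitting the
        ARI grid of a single pair).  Results are identical for any value.
    permutations
        Number of permutations for the significance test; 0 disables it.
    seed
        Seed for the permutation RNG.
    """

    kmax: int = 10
    jobs: int = 1
    permutations: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError(f"kmax must be >= 2, got {self.kmax}")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")


@dataclass(frozen=True, eq=False)
class CCCResult:
    """Coefficient value plus the maximizing partition pair.

    ``value`` is NaN when either variable is constant (undefined), 0.0 when a
    non-constant variable produced no valid partition.  ``labels_x`` /
    ``labels_y`` hold the maximizing partitions (the "red lines" one would
    draw on a scatterplot); they are None when no partition pair exists.
    """

    value: float
    kx: int
    ky: int
    labels_x: Optional[np.ndarray]
    labels_y: Optional[np.ndarray]
    p_value: Optional[float] = None

    @property
    def is_defined(self) -> bool:
        return not np.isnan(self.value)


def condensed_index(i: int, j: int, n_vars: int) -> int:
    """Map a pair (i, j), i < j, to its row-major upper-triangle index."""
    if not (0 <= i < j < n_vars):
        raise ValueError(f"need 0 <= i < j < n_vars, got i={i}, j={j}, n_vars={n_vars}")
    return n_vars * i - i * (i + 1) // 2 + (j - i - 1)


def condensed_to_pair(idx: int, n_vars: int) -> Tuple[int, int]:
    """Inverse of :func:`condensed_index`."""
    m = n_vars * (n_vars - 1) // 2
    if not (0 <= idx < m):
        raise ValueError(f"condensed index {idx} out of range for n_vars={n_vars}")
    i = 0
    while condensed_index(i, n_vars - 1, n_vars) < idx:
        i += 1
    j = idx - condensed_index(i, i + 1, n_vars) + i + 1
    return i, j


@dataclass(frozen=True, eq=False)
class CorrelationMatrix:
    """Condensed upper triangle of pairwise coefficients with variable names."""

    names: Tuple[str, ...]
    condensed: np.ndarray
    n_vars: int
    kx: np.ndarray
    ky: np.ndarray

    def value(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        a, b = (i, j) if i < j else (j, i)
        return float(self.condensed[condensed_index(a, b, self.n_vars)])

    def to_square(self) -> pd.DataFrame:
        """Square symmetric DataFrame; diagonal is 1.0 by convention."""
        mat = np.ones((self.n_vars, self.n_vars))
        iu = np.triu_indices(self.n_vars, k=1)
        mat[iu] = self.condensed
        mat[(iu[1], iu[0])] = self.condensed
        return pd.DataFrame(mat, index=list(self.names), columns=list(self.names))

    def to_pairs(self) -> pd.DataFrame:
        """Long-form pair list: gene_i, gene_j, ccc, kx, ky."""
        ii, jj = np.triu_indices(self.n_vars, k=1)
        return pd.DataFrame(
            {
                "gene_i": [self.names[i] for i in ii],
                "gene_j": [self.names[j] for j in jj],
                "ccc": self.condensed,
                "kx": self.kx,
                "ky": self.ky,
            }
        )


def _na_mask(v: DataVector) -> np.ndarray:
    if v.kind == NUMERICAL:
        return np.isnan(v.values)
    return pd.isna(v.values)


def _drop_na_pairwise(x: DataVector, y: DataVector) -> Tuple[DataVector, DataVector]:
    keep = ~(_na_mask(x) | _na_mask(y))
    return (
        DataVector(values=x.values[keep], kind=x.kind),
        DataVector(values=y.values[keep], kind=y.kind),
    )


def _grid_max(
    px: Sequence[Partition], py: Sequence[Partition], jobs: int = 1
) -> Tuple[float, Partition, Partition]:
    """Maximum ARI over the partition-pair grid, with a deterministic
    tie-break: among equal maxima prefer the smallest kx*ky, then kx."""
    pairs = [(a, b) for a in px for b in py]
    order = sorted(range(len(pairs)), key=lambda t: (pairs[t][0].k * pairs[t][1].k, pairs[t][0].k, pairs[t][1].k))
    if jobs != 1 and len(pairs) >= 8:
        chunks = np.array_split(np.asarray(order), max(1, min(len(order), 4 * jobs)))
        vals_chunks = Parallel(n_jobs=jobs)(
            delayed(_grid_chunk)(pairs, chunk.tolist()) for chunk in chunks
        )
        vals = [v for chunk in vals_chunks for v in chunk]
    else:
        vals = _grid_chunk(pairs, order)
    best_pos = 0
    for pos in range(1, len(vals)):
        if vals[pos] > vals[best_pos]:
            best_pos = pos
    a, b = pairs[order[best_pos]]
    return vals[best_pos], a, b


def _grid_chunk(pairs, indices) -> List[float]:
    return [
        _ari_from_labels(pairs[t][0].labels, pairs[t][0].k, pairs[t][1].labels, pairs[t][1].k)
        for t in indices
    ]


def ccc_pair(
    x: Union[DataVector, Sequence],
    y: Union[DataVector, Sequence],
    config: Optional[CCCConfig] = None,
    *,
    na_action: str = "raise",
) -> CCCResult:
    """Coefficient between two variables (any mix of numerical/categorical).

    Parameters
    ----------
    x, y
        DataVectors or raw sequences (numeric dtype -> numerical, anything
        else -> categorical).
    config
        See :class:`CCCConfig`.  With ``permutations > 0`` a permutation
        p-value is attached to the result.
    na_action
        ``"raise"`` (default) errors on missing values; ``"pairwise_complete"``
        drops objects missing in either variable before partitioning.
    """
    cfg = config if config is not None else CCCConfig()
    xv = as_data_vector(x)
    yv = as_data_vector(y)
    if xv.n != yv.n:
        raise ValueError(f"variables have different lengths: {xv.n} vs {yv.n}")
    if _na_mask(xv).any() or _na_mask(yv).any():
        if na_action == "pairwise_complete":
            xv, yv = _drop_na_pairwise(xv, yv)
        elif na_action == "raise":
            raise ValueError(
                "missing values present; pass na_action='pairwise_complete' to drop them"
            )
        else:
            raise ValueError(f"unknown na_action {na_action!r}")
    if xv.n < 2:
        raise ValueError(f"need at least 2 objects, got {xv.n}")
    if xv.is_constant or yv.is_constant:
        logger.warning("constant variable: coefficient is undefined")
        return CCCResult(value=float("nan"), kx=0, ky=0, labels_x=None, labels_y=None)
    px = generate_partitions(xv, cfg.kmax)
    py = generate_partitions(yv, cfg.kmax)
    if not px or not py:
        result = CCCResult(value=0.0, kx=0, ky=0, labels_x=None, labels_y=None)
    else:
        best, pa, pb = _grid_max(px.partitions, py.partitions, jobs=cfg.jobs)
        result = CCCResult(
            value=max(0.0, best),
            kx=pa.k,
            ky=pb.k,
            labels_x=pa.labels,
            labels_y=pb.labels,
        )
    if cfg.permutations > 0:
        from .significance import permutation_pvalue

        sig = permutation_pvalue(xv, yv, cfg)
        result = replace(result, p_value=sig.p_value)
    return result


def ccc(x, y, kmax: int = 10) -> float:
    """Convenience wrapper: the coefficient value only."""
    return ccc_pair(x, y, CCCConfig(kmax=kmax)).value


def _pair_value(
    psets: List[Optional[PartitionSet]], i: int, j: int
) -> Tuple[float, int, int]:
    pi, pj = psets[i], psets[j]
    if pi is None or pj is None:
        return float("nan"), 0, 0
    if not pi or not pj:
        return 0.0, 0, 0
    best, pa, pb = _grid_max(pi.partitions, pj.partitions)
    return max(0.0, best), pa.k, pb.k


def _matrix_chunk(psets, pairs) -> List[Tuple[float, int, int]]:
    return [_pair_value(psets, i, j) for i, j in pairs]


def ccc_matrix(
    rows: Sequence[Union[DataVector, Sequence]],
    config: Optional[CCCConfig] = None,
    names: Optional[Sequence[str]] = None,
) -> CorrelationMatrix:
    """Pairwise coefficients over all unordered row pairs of a matrix.

    Partition sets are derived once per variable and reused across pairs.
    The pair grid is split into chunks across ``config.jobs`` workers; the
    output is bit-identical for any worker count.  Constant rows produce NaN
    entries (with a warning) rather than failing the whole run.
    """
    cfg = config if config is not None else CCCConfig()
    vecs = [as_data_vector(r) for r in rows]
    if len(vecs) < 2:
        raise ValueError("need at least 2 rows")
    n = vecs[0].n
    for pos, v in enumerate(vecs):
        if v.n != n:
            raise ValueError(f"row {pos} has length {v.n}, expected {n}")
    if names is None:
        names = [f"var{i}" for i in range(len(vecs))]
    names = tuple(str(s) for s in names)
    if len(names) != len(vecs):
        raise ValueError("names and rows disagree in length")

    psets: List[Optional[PartitionSet]] = []
    for name, v in zip(names, vecs):
        if v.is_constant:
            logger.warning("variable %r is constant: its coefficients are undefined", name)
            psets.append(None)
        else:
            psets.append(generate_partitions(v, cfg.kmax))

    m = len(vecs)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    if cfg.jobs != 1 and len(pairs) > 1:
        chunk_arrays = np.array_split(np.arange(len(pairs)), max(1, min(len(pairs), 4 * abs(cfg.jobs))))
        results_chunks = Parallel(n_jobs=cfg.jobs)(
            delayed(_matrix_chunk)(psets, [pairs[t] for t in chunk]) for chunk in chunk_arrays
        )
        results = [r for chunk in results_chunks for r in chunk]
    else:
        results = _matrix_chunk(psets, pairs)

    condensed = np.array([r[0] for r in results], dtype=np.float64)
    kx = np.array([r[1] for r in results], dtype=np.int64)
    ky = np.array([r[2] for r in results], dtype=np.int64)
    return CorrelationMatrix(names=names, condensed=condensed, n_vars=m, kx=kx, ky=ky)
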