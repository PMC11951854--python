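"""Permutation significance for the coefficient, and FDR adjustment.

The null hypothesis is independence of the two variables.  One variable (y)
is permuted; the coefficient is recomputed for each permutation; the p-value
is the proportion of permuted coefficients greater than or equal to the
observed one.  An opt-in smoothed estimate, (r + 1) / (P + 1), never returns
exactly zero.

Permuting y and re-partitioning is equivalent to permuting the labels of
y's (unchanged) partitions, because quantile cutpoints depend only on the
multiset of values.  The implementation exploits this: partitions are built
once, label vectors are gathered through a (P, n) permutation matrix, and
all P adjusted Rand indices per partition pair are evaluated in one batched
contingency pass.  Computation is serial and vectorized, so the result
depends only on the seed, never on worker counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .ari import _ari_batch
from .coefficient import CCCConfig, ccc_pair
from .partitioning import DataVector, as_data_vector, generate_partitions


@dataclass(frozen=True)
class SignificanceResult:
    p_value: float
    n_permutations: int
    adjusted: Optional[float] = None


def permutation_pvalue(
    x: Union[DataVector, Sequence],
    y: Union[DataVector, Sequence],
    config: Optional[CCCConfig] = None,
    *,
    smoothing: bool = False,
) -> SignificanceResult:
    """Permutation p-value for the coefficient between x and y.

    ``config.permutations`` (>= 1) permutations of y are drawn from a single
    generator seeded with ``config.seed``.  Ties between permuted and
    observed values count toward the p-value (>=, taken literally).
    ``smoothing=True`` returns (r + 1) / (P + 1) instead of the plain
    proportion r / P.

    Raises when the observed coefficient is undefined (constant variable):
    there is no null to test.
    """
    cfg = config if config is not None else CCCConfig(permutations=10_000)
    if cfg.permutations < 1:
        raise ValueError("config.permutations must be >= 1 for a permutation test")
    xv = as_data_vector(x)
    yv = as_data_vector(y)
    observed = ccc_pair(xv, yv, replace(cfg, permutations=0))
    if not observed.is_defined:
        raise ValueError("coefficient is undefined (constant variable); no null to test")
    P = cfg.permutations
    px = generate_partitions(xv, cfg.kmax)
    py = generate_partitions(yv, cfg.kmax)
    if not px or not py:
        # observed value is 0 and every permuted value is 0 as well
        p = 1.0 if not smoothing else (P + 1) / (P + 1)
        return SignificanceResult(p_value=float(p), n_permutations=P)

    rng = np.random.default_rng(cfg.seed)
    n = xv.n
    perms = rng.permuted(np.tile(np.arange(n), (P, 1)), axis=1)
    best = np.full(P, -np.inf)
    for part_y in py:
        y_perm_labels = part_y.labels[perms]
        for part_x in px:
            np.maximum(
                best,
                _ari_batch(part_x.labels, part_x.k, y_perm_labels, part_y.k),
                out=best,
            )
    null = np.maximum(best, 0.0)
    r = int(np.count_nonzero(null >= observed.value))
    p = (r + 1) / (P + 1) if smoothing else r / P
    return SignificanceResult(p_value=float(p), n_permutations=P)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Standard step-up procedure with monotonicity enforcement; the output is
    aligned with the input order and satisfies ``adjusted >= raw``
    elementwise.
    """
    arr = np.asarray(p_values, dtype=np.float64)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(arr, method="bh")
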