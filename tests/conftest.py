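import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def anscombe_quartet():
    from clustercorr.synthetic import anscombe

    return anscombe()


def set_partitions(n):
    """All set partitions of n objects as restricted-growth label tuples."""
    out = []
    labels = [0] * n

    def rec(i, mx):
        if i == n:
            out.append(tuple(labels))
            return
        for lab in range(mx + 1):
            labels[i] = lab
            rec(i + 1, max(mx, lab + 1))

    if n == 1:
        return [(0,)]
    rec(1, 1)
    return out


def hubert_arabie_ari(la, lb):
    """Independent contingency-table ARI oracle (expected/max index form).

    Pure-python Hubert-Arabie formulation:
        (sum_ij C(n_ij,2) - E) / (0.5 (sum_a C(a_i,2) + sum_b C(b_j,2)) - E)
    with E the chance expectation.  Degenerate denominators (both partitions
    trivial in the same way) resolve to 1 for identical partitions.
    """
    from collections import Counter

    n = len(la)
    cont = Counter(zip(la, lb))
    a = Counter(la)
    b = Counter(lb)

    def comb2(m):
        return m * (m - 1) // 2

    sum_ij = sum(comb2(v) for v in cont.values())
    sum_a = sum(comb2(v) for v in a.values())
    sum_b = sum(comb2(v) for v in b.values())
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_ij == sum_a == sum_b else 0.0
    return (sum_ij - expected) / (max_index - expected)
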