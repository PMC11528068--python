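"""Independent reference implementations used only to check the package.

Each oracle is written directly from the defining sums, without reusing any
package code path it is meant to verify.
"""

from itertools import combinations
import math


def direct_sum_pearson(u, v) -> float:
    """Pearson correlation by explicit accumulation loops."""
    n = len(u)
    su = sv = 0.0
    for a, b in zip(u, v):
        su += a
        sv += b
    mu, mv = su / n, sv / n
    num = du2 = dv2 = 0.0
    for a, b in zip(u, v):
        num += (a - mu) * (b - mv)
        du2 += (a - mu) ** 2
        dv2 += (b - mv) ** 2
    if du2 == 0.0 or dv2 == 0.0:
        return 0.0
    return num / math.sqrt(du2 * dv2)


def hypergeom_enumeration(M: int, N: int, H: int, C: int) -> float:
    """P(overlap >= C) by enumerating every H-subset of M spots."""
    expressed = set(range(N))
    total = 0
    hits = 0
    for subset in combinations(range(M), H):
        total += 1
        if len(expressed.intersection(subset)) >= C:
            hits += 1
    return hits / total


def contingency_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from pair-counting over the contingency table."""
    from collections import Counter

    n = len(labels_a)
    table = Counter(zip(labels_a, labels_b))
    row = Counter(labels_a)
    col = Counter(labels_b)

    def c2(x):
        return x * (x - 1) // 2

    sum_ij = sum(c2(v) for v in table.values())
    sum_a = sum(c2(v) for v in row.values())
    sum_b = sum(c2(v) for v in col.values())
    expected = sum_a * sum_b / c2(n)
    max_idx = (sum_a + sum_b) / 2
    if max_idx == expected:
        return 1.0 if sum_ij == expected else 0.0
    return (sum_ij - expected) / (max_idx - expected)
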