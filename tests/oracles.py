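"""Independent oracles used by the test suite.

These are deliberately naive re-implementations (brute force, exact rational
arithmetic, hand-applied formulas) kept separate from the package code paths
they are used to check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_complete_linkage_partitions(D: np.ndarray) -> dict[int, set[frozenset]]:
    """O(n^3) complete-linkage agglomeration; partitions for every k.

    Ties broken by merging the pair whose smaller leaf index is smallest
    (then by the other cluster's smallest leaf index).
    """
    n = D.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    partitions = {n: set(clusters)}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                mi, mj = min(clusters[i]), min(clusters[j])
                key = (d, min(mi, mj), max(mi, mj))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        partitions[len(clusters)] = set(clusters)
    return partitions


def fisher_two_sided_fraction(table) -> float:
    """Two-sided exact 2×2 p-value via exact rational enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)

    def pr(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = pr(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pr(k) <= p_obs:
            total += pr(k)
    return float(total)


def bh_stepup_by_hand(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg: q_(i) = min_{j>=i} m p_(j)/j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def chi2_independence_by_hand(observed: np.ndarray) -> float:
    """Σ (O - E)^2 / E with E from the product of margins."""
    observed = np.asarray(observed, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    return float((((observed - expected) ** 2) / expected).sum())
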