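"""Independent brute-force reference implementations used only by tests.

Each function here recomputes a pipeline quantity by the most literal
method available — per-base loops, all-pairs interval checks, explicit
combinatorial sums, exhaustive permutation enumeration — deliberately
sharing no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def coverage_bruteforce(intervals, chrom: str, size: int) -> np.ndarray:
    """Per-base overlap count via an explicit loop over bases."""
    out = np.zeros(size)
    for c, s, e in intervals:
        if c != chrom:
            continue
        for pos in range(s, e):
            if 0 <= pos < size:
                out[pos] += 1.0
    return out


def window_mean_bruteforce(values: np.ndarray, start: int, end: int) -> float:
    total = 0.0
    for pos in range(start, end):
        total += float(values[pos])
    return total / (end - start)


def overlap_partition_bruteforce(a, b):
    """All-pairs any-overlap check; returns (a_shared, a_only, b_shared, b_only)."""

    def touches(x, y):
        return x[0] == y[0] and x[1] < y[2] and y[1] < x[2]

    a_shared = [p for p in a if any(touches(p, q) for q in b)]
    a_only = [p for p in a if not any(touches(p, q) for q in b)]
    b_shared = [q for q in b if any(touches(q, p) for p in a)]
    b_only = [q for q in b if not any(touches(q, p) for p in a)]
    return a_shared, a_only, b_shared, b_only


def transitions_bruteforce(ref_labels, alt_labels, classes):
    """Nested-loop transition counts keyed (ref class, alt class)."""
    counts = {(r, a): 0 for r in classes for a in classes}
    for r, a in zip(ref_labels, alt_labels):
        counts[(r, a)] += 1
    return counts


def hypergeom_uppertail_bruteforce(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n) by explicit combinatorial sum."""
    denom = math.comb(N, n)
    total = 0
    for i in range(x, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def wilcoxon_exact_bruteforce(a, b) -> float:
    """Two-sided exact rank-sum p via the pairwise-comparison U statistic.

    U is computed as the number of (a_i, b_j) pairs with a_i > b_j (half
    for ties); the null distribution enumerates every reassignment of the
    pooled observed values to the two groups.
    """

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yj in y:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    n1 = len(a)
    pooled = list(a) + list(b)
    center = n1 * (len(b)) / 2.0
    dev = abs(u_stat(a, b) - center)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        group_a = [pooled[i] for i in idx]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(group_a, group_b) - center) >= dev - 1e-9:
            hits += 1
        total += 1
    return hits / total


def hochberg_bruteforce(pvals) -> np.ndarray:
    """Hochberg step-up adjusted p values straight from the definition.

    With p_(1) <= ... <= p_(m), the adjusted value of p_(i) is
    min over j >= i of (m - j + 1) * p_(j), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank_i in range(m):
        candidates = [
            (m - rank_j) * p[order[rank_j]] for rank_j in range(rank_i, m)
        ]
        adj_sorted[rank_i] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj_sorted
    return out
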