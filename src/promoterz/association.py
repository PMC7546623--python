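"""Cross-signal association statistics.

Three building blocks used throughout the analysis:

* quartile partitioning of one per-promoter variable and comparison of a
  second variable across the quartiles;
* pairwise two-sided Wilcoxon rank-sum tests with Hochberg step-up
  adjustment across the pairs (exact permutation enumeration for small
  groups, tie-corrected normal approximation otherwise);
* any-overlap peak-set intersection with a hypergeometric upper-tail
  enrichment test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import PeakSet

__all__ = [
    "QUARTILES",
    "quartile_partition",
    "rank_sum_pairwise",
    "PeakOverlap",
    "intersect_peaks",
    "hypergeometric_overlap",
    "fc_by_quartile",
]

QUARTILES: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4")

#: largest group size for which the exact permutation rank-sum test is used
EXACT_MAX_N = 8


def quartile_partition(values: np.ndarray) -> np.ndarray:
    """Label each item Q1..Q4 by ascending rank of its value.

    Items are sorted ascending (stable, so ties keep input order) and cut
    into four contiguous rank blocks; Q4 holds the highest values.  When n
    is not divisible by 4 the earlier quartiles receive the extra items
    (largest-remainder rule), so group sizes differ by at most one.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError(f"need at least 4 values, got {n}")
    order = np.argsort(values, kind="stable")
    base, extra = divmod(n, 4)
    sizes = [base + (1 if i < extra else 0) for i in range(4)]
    labels = np.empty(n, dtype=object)
    pos = 0
    for name, size in zip(QUARTILES, sizes):
        labels[order[pos : pos + size]] = name
        pos += size
    return labels


def _rank_sum_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    The null distribution is the permutation distribution of the
    Mann-Whitney U statistic over all ways of labelling the pooled observed
    values, which handles ties exactly.  Two-sided p is the probability of
    a U at least as far from its null mean as observed.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center) - 1e-9  # tolerate float fuzz in tied ranks
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - offset
        if abs(u - center) >= dev:
            hits += 1
        total += 1
    return u_obs, hits / total


def rank_sum_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise two-sided Wilcoxon rank-sum tests with Hochberg adjustment.

    For each unordered pair of groups the Mann-Whitney U of the first group
    is reported with its two-sided p: exact permutation enumeration when
    both groups have at most ``EXACT_MAX_N`` observations, tie-corrected
    normal approximation otherwise.  P values are adjusted across all pairs
    with the Hochberg step-up procedure.  Returns columns ``group_a,
    group_b, statistic, p_raw, p_adj, n_a, n_b``.
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        a, b = arrays[ga], arrays[gb]
        if len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N:
            stat, p = _rank_sum_exact_p(a, b)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"group_a": ga, "group_b": gb, "statistic": stat, "p_raw": p,
             "n_a": len(a), "n_b": len(b)}
        )
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw", "n_a", "n_b"])
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method="simes-hochberg")[1]
    else:
        df["p_adj"] = np.array([], dtype=float)
    return df[["group_a", "group_b", "statistic", "p_raw", "p_adj", "n_a", "n_b"]]


@dataclass
class PeakOverlap:
    """Any-overlap partition of two peak sets, from both perspectives.

    A peak is "shared" if it overlaps any peak of the other set by at least
    one base (half-open intervals, so mere abutment does not count).  The
    shared relation is symmetric but the shared *counts* are reported per
    side, since several peaks of one set can hit one peak of the other.
    """

    a_shared: PeakSet
    a_only: PeakSet
    b_shared: PeakSet
    b_only: PeakSet

    @property
    def shared(self) -> PeakSet:
        return self.a_shared

    def venn_counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "a_shared": len(self.a_shared),
            "b_shared": len(self.b_shared),
        }


def _trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in peaks:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def intersect_peaks(a: PeakSet, b: PeakSet) -> PeakOverlap:
    """Partition two peak sets by the any-overlap relation."""
    trees_b = _trees(b)
    trees_a = _trees(a)

    def split(peaks: PeakSet, other: dict[str, IntervalTree]) -> tuple[list, list]:
        hit, miss = [], []
        for chrom, start, end in peaks:
            tree = other.get(chrom)
            if tree is not None and tree.overlap(start, end):
                hit.append((chrom, start, end))
            else:
                miss.append((chrom, start, end))
        return hit, miss

    a_hit, a_miss = split(a, trees_b)
    b_hit, b_miss = split(b, trees_a)
    return PeakOverlap(
        a_shared=PeakSet(a_hit, label=f"{a.label} shared"),
        a_only=PeakSet(a_miss, label=f"{a.label} only"),
        b_shared=PeakSet(b_hit, label=f"{b.label} shared"),
        b_only=PeakSet(b_miss, label=f"{b.label} only"),
    )


def hypergeometric_overlap(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric p for an overlap of x items.

    Probability of drawing at least ``x`` of the ``K`` marked items in a
    sample of ``n`` from a universe of ``N``.  The universe must be chosen
    by the caller (for peak overlaps, e.g. the number of promoters or
    testable regions considered).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not (max(0, K + n - N) <= x <= min(K, n)):
        raise ValueError(f"overlap x={x} impossible for N={N}, K={K}, n={n}")
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def fc_by_quartile(
    partition_values: pd.Series,
    response_values: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quartile one variable, compare another across the quartiles.

    Both series must be indexed by the same promoter ids.  The first is cut
    into quartiles; the second is compared across them with pairwise
    rank-sum tests.  Returns ``(assignments, comparisons)`` where
    ``assignments`` has columns ``gene_id, quartile, response``.
    """
    if set(partition_values.index) != set(response_values.index):
        diff = len(set(partition_values.index) ^ set(response_values.index))
        raise ValueError(f"promoter ids differ between the two variables ({diff} mismatched)")
    response = response_values.reindex(partition_values.index)
    labels = quartile_partition(partition_values.to_numpy())
    assignments = pd.DataFrame(
        {
            "gene_id": partition_values.index.to_numpy(),
            "quartile": labels,
            "response": response.to_numpy(dtype=float),
        }
    )
    groups = {
        qname: assignments.loc[assignments["quartile"] == qname, "response"].to_numpy()
        for qname in QUARTILES
    }
    comparisons = rank_sum_pairwise(groups)
    return assignments, comparisons
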