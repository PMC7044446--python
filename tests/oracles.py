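"""Independent brute-force oracles used to verify the package implementations.

Everything here is deliberately naive (exact rational arithmetic, double
loops, O(n^3) agglomeration) and shares no code with the package.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration in exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    probs = [
        Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(kmin, kmax + 1)
    ]
    p_obs = probs[a - kmin]
    return float(sum(p for p in probs if p <= p_obs))


def recount_coverage_filter(tables, min_cov):
    """Dict-based recount of the joint coverage filter.

    ``tables`` is a list of {(chrom, pos): (coverage, meth)} dicts; returns
    the sorted list of keys kept.
    """
    keys = set(tables[0])
    for t in tables[1:]:
        keys &= set(t)
    kept = [k for k in sorted(keys) if all(t[k][0] >= min_cov for t in tables)]
    return kept


def overlap_count_loop(points, intervals) -> int:
    """Double-loop point-in-interval count (half-open intervals)."""
    n = 0
    for chrom, pos in points:
        for (ichrom, start, end) in intervals:
            if ichrom == chrom and start <= pos < end:
                n += 1
                break
    return n


def occupancy_profile_loop(track_rows, anchors, flank):
    """Per-offset mean of a bedGraph over anchors, by linear scan."""
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(len(offsets))
    for (achrom, apos) in anchors:
        for j, off in enumerate(offsets):
            p = apos + off
            val = 0.0
            for (chrom, start, end, value) in track_rows:
                if chrom == achrom and start <= p < end:
                    val = value
                    break
            acc[j] += val
    return offsets, acc / len(anchors)


def complete_linkage_partition(x, k):
    """Naive O(n^3) complete-linkage agglomeration cut at k clusters.

    Returns the partition as a set of frozensets of row indices.
    """
    x = np.asarray(x, dtype=float)
    clusters = [{i} for i in range(len(x))]
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    np.linalg.norm(x[a] - x[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def pca_eig_oracle(x):
    """Explained-variance fractions via eigendecomposition of the sample Gram.

    ``x`` is samples x variables; variables are mean-centered, no scaling.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    gram = xc @ xc.T / (n - 1)
    ev = np.sort(np.linalg.eigvalsh(gram))[::-1]
    ev = np.clip(ev, 0, None)[: n - 1]
    total = ev.sum()
    return ev / total if total > 0 else ev


def partition_of(labels):
    """Group row indices by label into a comparable set-of-frozensets."""
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}
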