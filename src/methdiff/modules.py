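"""DMP module clustering and nucleosome-occupancy profile aggregation.

DMPs are clustered on their per-condition mean methylation rate vectors
with agglomerative hierarchical clustering (complete linkage, Euclidean
distance) and the tree is cut to a fixed number of groups; the resulting
clusters are the "modules". Occupancy profiles average a bedGraph track in
a window around each module CpG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "OccupancyProfile",
    "cluster_dmps",
    "occupancy_profile",
    "summarize_modules",
]

_CLUSTER_GUARD = 100_000


def cluster_dmps(rate_profiles: pd.DataFrame, k: int = 12) -> pd.Series:
    """Assign each DMP to one of ``k`` modules.

    ``rate_profiles`` is a DMP x condition matrix of methylation rates.
    Labels are integers 1..k, renumbered by order of first appearance in the
    input, so the assignment is deterministic for a fixed row order and the
    induced partition is invariant under row permutation.
    """
    x = rate_profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if np.isnan(x).any():
        raise ValueError("missing rates in clustering input")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot cut {n} DMPs into {k} modules")
    if n > _CLUSTER_GUARD:
        raise ValueError(
            f"{n} DMPs exceeds the clustering guard ({_CLUSTER_GUARD}); "
            "subsample first (complete linkage is O(n^2) in memory)"
        )
    if k == 1:
        raw = np.ones(n, dtype=np.int64)
    elif k == n:
        raw = np.arange(1, n + 1, dtype=np.int64)
    else:
        z = linkage(x, method="complete", metric="euclidean")
        raw = fcluster(z, t=k, criterion="maxclust")
    # renumber by first appearance
    _, first_pos = np.unique(raw, return_index=True)
    order = {raw[i]: rank + 1 for rank, i in enumerate(sorted(first_pos))}
    labels = np.array([order[r] for r in raw], dtype=np.int64)
    return pd.Series(labels, index=rate_profiles.index, name="module")


def summarize_modules(
    labels: pd.Series, rate_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Per-module size and mean methylation rate per condition."""
    if not labels.index.equals(rate_profiles.index):
        raise ValueError("labels and rate_profiles must share an index")
    df = rate_profiles.copy()
    df["module"] = labels.to_numpy()
    g = df.groupby("module", sort=True)
    means = g.mean()
    means.insert(0, "size", g.size())
    return means.reset_index()


@dataclass
class OccupancyProfile:
    """Mean track value per offset around a set of anchor positions."""

    offsets: np.ndarray
    mean: np.ndarray
    n_anchors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean})


def _step_lookup(track: pd.DataFrame):
    """Per-chromosome step-function lookup for a (non-overlapping) bedGraph."""
    by_chrom = {}
    for chrom, grp in track.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        by_chrom[chrom] = (
            g["start"].to_numpy(np.int64),
            g["end"].to_numpy(np.int64),
            g["value"].to_numpy(float),
        )

    def lookup(chrom: str, positions: np.ndarray) -> np.ndarray:
        if chrom not in by_chrom:
            return np.zeros(len(positions))
        starts, ends, values = by_chrom[chrom]
        i = np.searchsorted(starts, positions, side="right") - 1
        ok = (i >= 0) & (positions < ends[np.clip(i, 0, len(ends) - 1)])
        out = np.zeros(len(positions))
        out[ok] = values[i[ok]]
        return out

    return lookup


def occupancy_profile(
    track: pd.DataFrame,
    anchors: pd.DataFrame,
    flank: int = 1000,
) -> OccupancyProfile:
    """Average a bedGraph track over +/-``flank`` bp around anchor CpGs.

    ``track`` has columns chrom, start, end, value (non-overlapping
    intervals); ``anchors`` has columns chrom, pos. Offsets run from
    -flank to +flank at 1 bp; positions not covered by the track (including
    offsets running off the contig start) contribute 0.
    """
    if anchors.empty:
        raise ValueError("no anchors")
    offsets = np.arange(-flank, flank + 1)
    lookup = _step_lookup(track)
    acc = np.zeros(len(offsets))
    for chrom, grp in anchors.groupby("chrom", sort=False):
        for pos in grp["pos"].to_numpy(np.int64):
            acc += lookup(chrom, pos + offsets)
    return OccupancyProfile(
        offsets=offsets, mean=acc / len(anchors), n_anchors=len(anchors)
    )
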