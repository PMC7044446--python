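"""Five-step sliding-window DMR extraction.

Steps: (1) build overlapping 3-CpG windows (step of one CpG, max span 2 kb)
with per-condition mean coverage and mean methylated calls; (2) Fisher-test
each window on its rounded averaged counts; (3) merge runs of consecutive
significant windows of one direction; (4) re-test each merged region on its
summed counts; (5) keep regions with >= 3 member windows and
>= 3 CpGs per kb of span.

Because the window step is one CpG, three consecutive windows span exactly
five CpGs, so the minimum-window filter also enforces >= 5 CpGs per DMR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from methdiff.dmp import _fisher_many, two_sided_fisher

__all__ = [
    "build_windows",
    "call_dmrs",
    "filter_dmrs",
    "merge_windows",
    "retest_regions",
    "test_windows",
]

WINDOW_COLUMNS = [
    "chrom", "idx", "start", "end",
    "mean_cov_a", "mean_meth_a", "mean_cov_b", "mean_meth_b",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # counts are non-negative, so half-away-from-zero == floor(x + 0.5)
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def build_windows(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    window_cpgs: int = 3,
    max_span: int = 2000,
) -> pd.DataFrame:
    """One window per consecutive CpG triple (step = 1 CpG) within a chromosome.

    ``idx`` is the index of the window's first CpG within its chromosome.
    Windows whose span (last CpG position + 1 - first position) exceeds
    ``max_span`` are skipped. Stores per-condition mean coverage and mean
    methylated calls over the member CpGs.
    """
    if window_cpgs < 2:
        raise ValueError("window_cpgs must be >= 2")
    if len(counts_a) != len(counts_b) or not (
        counts_a["pos"].to_numpy() == counts_b["pos"].to_numpy()
    ).all():
        raise ValueError("pooled frames do not share a position index")
    rows = []
    for chrom, grp_a in counts_a.groupby("chrom", sort=True):
        pos = grp_a["pos"].to_numpy()
        if (np.diff(pos) <= 0).any():
            raise ValueError(f"positions not strictly increasing on {chrom}")
        grp_b = counts_b[counts_b["chrom"] == chrom]
        cov_a = grp_a["coverage"].to_numpy(dtype=float)
        meth_a = grp_a["meth_calls"].to_numpy(dtype=float)
        cov_b = grp_b["coverage"].to_numpy(dtype=float)
        meth_b = grp_b["meth_calls"].to_numpy(dtype=float)
        w = window_cpgs
        n = len(pos)
        if n < w:
            continue
        starts = pos[: n - w + 1]
        ends = pos[w - 1:] + 1
        span_ok = (ends - starts) <= max_span
        kern = np.ones(w) / w
        mca = np.convolve(cov_a, kern, mode="valid")
        mma = np.convolve(meth_a, kern, mode="valid")
        mcb = np.convolve(cov_b, kern, mode="valid")
        mmb = np.convolve(meth_b, kern, mode="valid")
        for i in np.flatnonzero(span_ok):
            rows.append(
                (chrom, int(i), int(starts[i]), int(ends[i]),
                 mca[i], mma[i], mcb[i], mmb[i], w)
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS + ["window_cpgs"])


def test_windows(windows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher-test each window on rounded averaged counts; keep p <= alpha.

    Averaged counts are rounded half away from zero to form an integer 2x2
    table. Direction is the sign of the averaged rate difference
    (condition b minus condition a).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if windows.empty:
        out = windows.copy()
        out["p_value"] = pd.Series(dtype=float)
        out["direction"] = pd.Series(dtype=str)
        return out
    ca = _round_half_away(windows["mean_cov_a"])
    ma = _round_half_away(windows["mean_meth_a"])
    cb = _round_half_away(windows["mean_cov_b"])
    mb = _round_half_away(windows["mean_meth_b"])
    assert (ma <= ca).all() and (mb <= cb).all()
    p = _fisher_many(ma, ca - ma, mb, cb - mb)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = windows["mean_meth_b"].to_numpy() / windows["mean_cov_b"].to_numpy() \
            - windows["mean_meth_a"].to_numpy() / windows["mean_cov_a"].to_numpy()
    out = windows.copy()
    out["p_value"] = p
    out["direction"] = np.where(delta > 0, "hyper", np.where(delta < 0, "hypo", "none"))
    return out[out["p_value"] <= alpha].reset_index(drop=True)


def merge_windows(sig_windows: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of consecutive same-direction significant windows.

    Windows are continuous when their first-CpG indices are consecutive
    (they then share two CpGs); a gap of even one window index, or a change
    of direction, starts a new region. Returns per region the chromosome,
    member CpG index range, bounds, member-window count and direction.
    """
    cols = ["chrom", "first_idx", "last_idx", "start", "end", "n_windows", "direction"]
    if sig_windows.empty:
        return pd.DataFrame(columns=cols)
    sw = sig_windows.sort_values(["chrom", "idx"], kind="mergesort")
    rows = []
    for (chrom, direction), grp in sw.groupby(["chrom", "direction"], sort=True):
        idx = grp["idx"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        breaks = np.flatnonzero(np.diff(idx) != 1)
        run_bounds = np.concatenate([[0], breaks + 1, [len(idx)]])
        window_cpgs = int(grp["window_cpgs"].iloc[0]) if "window_cpgs" in grp else 3
        for lo, hi in zip(run_bounds[:-1], run_bounds[1:]):
            if hi <= lo:
                continue
            rows.append(
                (
                    chrom,
                    int(idx[lo]),
                    int(idx[hi - 1] + window_cpgs - 1),
                    int(starts[lo:hi].min()),
                    int(ends[lo:hi].max()),
                    int(hi - lo),
                    direction,
                )
            )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def retest_regions(
    regions: pd.DataFrame,
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Second-pass Fisher on counts summed over each region's member CpGs."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if regions.empty:
        out = regions.copy()
        for c in ("p_value", "mean_delta"):
            out[c] = pd.Series(dtype=float)
        out["n_cpgs"] = pd.Series(dtype=np.int64)
        return out
    rows = []
    grouped_a = {c: g for c, g in counts_a.groupby("chrom", sort=False)}
    grouped_b = {c: g for c, g in counts_b.groupby("chrom", sort=False)}
    for reg in regions.itertuples(index=False):
        ga = grouped_a[reg.chrom]
        gb = grouped_b[reg.chrom]
        sl = slice(reg.first_idx, reg.last_idx + 1)
        ca = int(ga["coverage"].to_numpy()[sl].sum())
        ma = int(ga["meth_calls"].to_numpy()[sl].sum())
        cb = int(gb["coverage"].to_numpy()[sl].sum())
        mb = int(gb["meth_calls"].to_numpy()[sl].sum())
        if ca == 0 or cb == 0:
            raise ValueError("empty region in retest")
        p = two_sided_fisher(ma, ca - ma, mb, cb - mb)
        rows.append((p, mb / cb - ma / ca, reg.last_idx - reg.first_idx + 1))
    extra = pd.DataFrame(rows, columns=["p_value", "mean_delta", "n_cpgs"])
    out = pd.concat([regions.reset_index(drop=True), extra], axis=1)
    return out[out["p_value"] <= alpha].reset_index(drop=True)


def filter_dmrs(
    regions: pd.DataFrame,
    min_density: float = 3.0,
    min_windows: int = 3,
) -> pd.DataFrame:
    """Apply the CpG-density and minimum-window filters; emit DMR records.

    Density is n_cpgs per kb of span, span = last CpG position - first CpG
    position + 1 (equal to end - start). With a one-CpG window step,
    ``min_windows=3`` implies >= 5 member CpGs.
    """
    if regions.empty:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_cpgs", "n_windows",
                "density", "p_value", "mean_delta", "direction",
            ]
        )
    span = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    density = regions["n_cpgs"].to_numpy() / (span / 1000.0)
    keep = (density >= min_density) & (regions["n_windows"].to_numpy() >= min_windows)
    out = regions.loc[keep].reset_index(drop=True).copy()
    out["density"] = density[keep]
    return out[
        ["chrom", "start", "end", "n_cpgs", "n_windows",
         "density", "p_value", "mean_delta", "direction"]
    ]


def call_dmrs(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    alpha: float = 0.05,
    window_cpgs: int = 3,
    max_span: int = 2000,
    min_density: float = 3.0,
    min_windows: int = 3,
) -> pd.DataFrame:
    """Run the full DMR procedure: build, test, merge, re-test, filter."""
    windows = build_windows(counts_a, counts_b, window_cpgs, max_span)
    sig = test_windows(windows, alpha)
    regions = merge_windows(sig)
    retested = retest_regions(regions, counts_a, counts_b, alpha)
    return filter_dmrs(retested, min_density, min_windows)
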