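"""Per-CpG two-condition Fisher exact testing and sample-level PCA.

The two-sided Fisher p-value is the sum over all 2x2 tables with the
observed margins whose hypergeometric probability does not exceed the
observed table's probability, with a relative tolerance of 1e-7 on the
comparison to absorb floating-point ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "PCAResult",
    "fisher_dmp",
    "fisher_test_counts",
    "methylation_pca",
    "pool_condition_counts",
    "two_sided_fisher",
    "union_dmps",
]

_TIE_RTOL = 1e-7


def two_sided_fisher(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(
        _fisher_many(
            np.asarray([a]), np.asarray([b]), np.asarray([c]), np.asarray([d])
        )[0]
    )


def _fisher_many(a, b, c, d) -> np.ndarray:
    """Vector of two-sided Fisher p-values for tables [[a_i,b_i],[c_i,d_i]]."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if (np.minimum.reduce([a, b, c, d]) < 0).any():
        raise ValueError("negative cell in 2x2 table")
    r1 = a + b
    r2 = c + d
    c1 = a + c
    n = r1 + r2
    out = np.empty(len(a), dtype=float)
    lg_const = (
        gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1) + gammaln(n - c1 + 1)
        - gammaln(n + 1)
    )
    for i in range(len(a)):
        kmin = max(0, c1[i] - r2[i])
        kmax = min(c1[i], r1[i])
        k = np.arange(kmin, kmax + 1)
        logpmf = lg_const[i] - (
            gammaln(k + 1)
            + gammaln(r1[i] - k + 1)
            + gammaln(c1[i] - k + 1)
            + gammaln(r2[i] - c1[i] + k + 1)
        )
        pmf = np.exp(logpmf)
        p_obs = pmf[a[i] - kmin]
        out[i] = min(1.0, pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return out


def pool_condition_counts(tables: list, condition: str) -> pd.DataFrame:
    """Sum (coverage, meth_calls) per position over all samples of a condition.

    Tables must already share a position index (apply the joint coverage
    filter first). Returns columns chrom, pos, coverage, meth_calls.
    """
    sel = [t for t in tables if t.condition == condition]
    if not sel:
        raise ValueError(f"no tables with condition {condition!r}")
    ref = sel[0].data[["chrom", "pos"]]
    for t in sel[1:]:
        if len(t.data) != len(ref) or not (
            t.data["chrom"].to_numpy() == ref["chrom"].to_numpy()
        ).all() or not (t.data["pos"].to_numpy() == ref["pos"].to_numpy()).all():
            raise ValueError("tables do not share a position index; filter first")
    pooled = ref.copy()
    pooled["coverage"] = sum(t.data["coverage"].to_numpy() for t in sel)
    pooled["meth_calls"] = sum(t.data["meth_calls"].to_numpy() for t in sel)
    return pooled


def fisher_test_counts(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-position two-sided Fisher p over two pooled count frames.

    Returns the shared positions with pooled counts, rates, delta
    (rate_b - rate_a) and p_value for *every* position (no alpha cut).
    """
    if len(counts_a) != len(counts_b) or not (
        counts_a["pos"].to_numpy() == counts_b["pos"].to_numpy()
    ).all():
        raise ValueError("pooled frames do not share a position index")
    cov_a = counts_a["coverage"].to_numpy(dtype=np.int64)
    meth_a = counts_a["meth_calls"].to_numpy(dtype=np.int64)
    cov_b = counts_b["coverage"].to_numpy(dtype=np.int64)
    meth_b = counts_b["meth_calls"].to_numpy(dtype=np.int64)
    if (cov_a <= 0).any() or (cov_b <= 0).any():
        raise ValueError("all pooled coverages must be > 0")
    p = _fisher_many(meth_a, cov_a - meth_a, meth_b, cov_b - meth_b)
    rate_a = meth_a / cov_a
    rate_b = meth_b / cov_b
    return pd.DataFrame(
        {
            "chrom": counts_a["chrom"].to_numpy(),
            "pos": counts_a["pos"].to_numpy(),
            "cov_a": cov_a,
            "meth_a": meth_a,
            "cov_b": cov_b,
            "meth_b": meth_b,
            "rate_a": rate_a,
            "rate_b": rate_b,
            "delta": rate_b - rate_a,
            "p_value": p,
        }
    )


def fisher_dmp(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Call DMPs between two pooled conditions at significance ``alpha``.

    Each CpG is tested with a two-sided Fisher exact test on the 2x2 table
    [[meth_a, unmeth_a], [meth_b, unmeth_b]]; positions with p <= alpha are
    returned with delta = rate_b - rate_a and direction "hyper" (delta > 0)
    or "hypo" (delta < 0). CpGs with p <= alpha but delta == 0 are not
    called (direction undefined). No multiple-testing correction is applied
    by default; ``fdr=True`` switches the alpha cut to Benjamini-Hochberg
    adjusted p-values.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    res = fisher_test_counts(counts_a, counts_b)
    pcol = res["p_value"].to_numpy()
    if fdr:
        pcol = _bh_adjust(pcol)
        res = res.assign(p_adjusted=pcol)
    keep = (pcol <= alpha) & (res["delta"].to_numpy() != 0)
    out = res[keep].reset_index(drop=True)
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def union_dmps(dmp_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """De-duplicated union of DMP positions over named comparisons.

    Returns one row per (chrom, pos) with a ``comparisons`` column listing
    the contributing comparison names (comma-joined, sorted).
    """
    frames = []
    for name, df in dmp_sets.items():
        f = df[["chrom", "pos"]].copy()
        f["comparison"] = name
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "comparisons"])
    cat = pd.concat(frames, ignore_index=True)
    out = (
        cat.groupby(["chrom", "pos"], sort=True)["comparison"]
        .apply(lambda s: ",".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"comparison": "comparisons"})
    )
    return out


@dataclass
class PCAResult:
    """Sample scores and explained-variance fractions of a methylation PCA."""

    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if len(evr) and (np.diff(evr) > 1e-12).any():
            raise ValueError("explained-variance fractions must be non-increasing")
        self.explained_variance_ratio = evr


def methylation_pca(rate_matrix: pd.DataFrame) -> PCAResult:
    """PCA of a positions x samples rate matrix, samples as observations.

    CpG rates are the variables: each position is mean-centered across
    samples and no variance scaling is applied. Missing rates are an error;
    apply the joint coverage filter first.
    """
    if rate_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = rate_matrix.to_numpy(dtype=float).T  # samples x positions
    if np.isnan(x).any():
        raise ValueError("missing rates present; filter positions first")
    n = x.shape[0]
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    n_comp = min(n - 1, x.shape[1])
    u, s = u[:, :n_comp], s[:n_comp]
    var = s**2 / (n - 1)
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        u * s,
        index=rate_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return PCAResult(scores=scores, explained_variance_ratio=evr)
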