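"""Methylation-expression integration.

Selects genes whose promoter-proxy region (2 kb upstream to 1 kb downstream
of the transcription start) contains differentially methylated CpGs,
correlates promoter methylation with expression across conditions, and
links distal DMPs to genes through chromatin-interaction anchor pairs.

Correlations are Pearson r over the (typically three) condition values;
with so few points r is descriptive, not inferential.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from methdiff.meth_io import FeatureSet
from methdiff.enrichment import _membership

__all__ = [
    "correlate_meth_expr",
    "correlation_histogram",
    "link_distal",
    "log2_fold_change",
    "select_candidates",
    "tss_region",
]


def tss_region(
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    up: int = 2000,
    down: int = 1000,
    strand_aware: bool = True,
) -> tuple[str, int, int]:
    """Promoter-proxy interval: ``up`` bp upstream to ``down`` bp downstream
    of the transcription start, clipped at the contig start.

    With ``strand_aware=False`` the gene's ``start`` coordinate is used as
    the TSS regardless of strand (the literal reading of "start of the
    gene"); by default the biological TSS (``end`` on the minus strand) is
    used.
    """
    if strand_aware and strand == "-":
        lo, hi = end - down, end + up
    else:
        lo, hi = start - up, start + down
    return chrom, max(0, lo), hi


def log2_fold_change(expr_a: float, expr_b: float, pseudocount: float = 1.0) -> float:
    """log2((expr_b + pseudocount) / (expr_a + pseudocount))."""
    if expr_a < 0 or expr_b < 0:
        raise ValueError("expression values must be non-negative")
    return float(np.log2((expr_b + pseudocount) / (expr_a + pseudocount)))


def correlate_meth_expr(meth, expr) -> float:
    """Pearson r between paired per-condition methylation and expression.

    Returns NaN when either vector has zero variance.
    """
    m = np.asarray(meth, dtype=float)
    e = np.asarray(expr, dtype=float)
    if len(m) != len(e):
        raise ValueError("methylation and expression vectors differ in length")
    if len(m) < 2:
        raise ValueError("need at least 2 paired conditions")
    # constant vectors (up to float noise in the mean) have no defined r
    if np.allclose(m, m[0], rtol=0, atol=1e-12) or np.allclose(e, e[0], rtol=0, atol=1e-12):
        return float("nan")
    mc = m - m.mean()
    ec = e - e.mean()
    return float((mc * ec).sum() / math.sqrt((mc**2).sum() * (ec**2).sum()))


def _genes_tss_frame(
    genes: pd.DataFrame, up: int, down: int, strand_aware: bool
) -> pd.DataFrame:
    rows = []
    for g in genes.itertuples(index=False):
        chrom, lo, hi = tss_region(
            g.chrom, g.start, g.end, g.strand, up, down, strand_aware
        )
        rows.append((g.gene_id, chrom, lo, hi))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss_start", "tss_end"])


def select_candidates(
    dmps: pd.DataFrame,
    rates: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    tfbs: FeatureSet | None = None,
    min_delta: float = 0.2,
    min_lfc: float = 1.5,
    up: int = 2000,
    down: int = 1000,
    strand_aware: bool = True,
    conditions: list[str] | None = None,
):
    """Candidate genes: |log2 fold change| >= ``min_lfc`` between the two
    conditions and >= 1 qualifying DMP in the TSS region.

    A qualifying DMP has |delta| >= ``min_delta`` and lies inside a TFBS
    interval (the TFBS filter is skipped, with a warning, when ``tfbs`` is
    None). ``dmps`` needs columns chrom, pos, delta; ``rates`` carries
    per-condition rate columns aligned to chrom, pos and is used for the
    per-gene correlation of mean TSS methylation with expression over
    ``conditions`` (default: every condition column of ``expression``).

    Returns ``(candidates, associations)``: one row per selected gene with
    its fold change, per-condition mean TSS methylation and Pearson r, and
    the underlying gene-DMP pairs.
    """
    if conditions is None:
        conditions = list(expression.columns)
    qual = dmps[np.abs(dmps["delta"].to_numpy()) >= min_delta].reset_index(drop=True)
    if tfbs is None:
        warnings.warn("no TFBS set supplied; TFBS membership filter skipped")
    elif len(qual):
        qual = qual[_membership(qual[["chrom", "pos"]], tfbs)].reset_index(drop=True)
    qual = qual.merge(rates, on=["chrom", "pos"], how="left")

    tssf = _genes_tss_frame(genes, up, down, strand_aware)
    cand_rows, assoc_rows = [], []
    for g in tssf.itertuples(index=False):
        if g.gene_id not in expression.index:
            continue
        lfc = log2_fold_change(
            float(expression.at[g.gene_id, cond_a]),
            float(expression.at[g.gene_id, cond_b]),
        )
        if abs(lfc) < min_lfc:
            continue
        hits = qual[
            (qual["chrom"] == g.chrom)
            & (qual["pos"] >= g.tss_start)
            & (qual["pos"] < g.tss_end)
        ]
        if hits.empty:
            continue
        mean_meth = {c: float(hits[c].mean()) for c in conditions}
        expr = [float(expression.at[g.gene_id, c]) for c in conditions]
        r = correlate_meth_expr([mean_meth[c] for c in conditions], expr)
        cand_rows.append(
            {
                "gene_id": g.gene_id,
                "lfc": lfc,
                "n_dmps": len(hits),
                **{f"meth_{c}": mean_meth[c] for c in conditions},
                "r": r,
            }
        )
        for h in hits.itertuples(index=False):
            assoc_rows.append(
                {"gene_id": g.gene_id, "chrom": h.chrom, "pos": h.pos,
                 "delta": h.delta, "lfc": lfc}
            )
    candidates = pd.DataFrame(
        cand_rows,
        columns=["gene_id", "lfc", "n_dmps"]
        + [f"meth_{c}" for c in conditions] + ["r"],
    )
    associations = pd.DataFrame(
        assoc_rows, columns=["gene_id", "chrom", "pos", "delta", "lfc"]
    )
    return candidates, associations


def correlation_histogram(
    r_values, bins: int = 20
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of correlation coefficients over [-1, 1].

    Returns (counts, bin_edges, n_missing); NaN values are excluded from
    the histogram and counted separately.
    """
    r = np.asarray(list(r_values), dtype=float)
    missing = int(np.isnan(r).sum())
    counts, edges = np.histogram(r[~np.isnan(r)], bins=bins, range=(-1.0, 1.0))
    return counts, edges, missing


def link_distal(
    dmps: pd.DataFrame,
    rates: pd.DataFrame,
    interactions: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    conditions: list[str] | None = None,
    up: int = 2000,
    down: int = 1000,
    strand_aware: bool = True,
    r_threshold: float = 0.7,
) -> pd.DataFrame:
    """Pair DMPs in one interaction anchor with genes whose TSS region
    overlaps the partner anchor; correlate DMP methylation with the gene's
    expression across conditions.

    Links with |r| >= ``r_threshold`` are flagged ``strong``. Both anchor
    orientations are considered.
    """
    if conditions is None:
        conditions = list(expression.columns)
    d = dmps.merge(rates, on=["chrom", "pos"], how="left")
    tssf = _genes_tss_frame(genes, up, down, strand_aware)
    rows = []
    for pair in interactions.itertuples(index=False):
        anchors = (
            (pair.chromA, pair.startA, pair.endA, pair.chromB, pair.startB, pair.endB),
            (pair.chromB, pair.startB, pair.endB, pair.chromA, pair.startA, pair.endA),
        )
        for (dc, ds, de, gc, gs, ge) in anchors:
            in_anchor = d[(d["chrom"] == dc) & (d["pos"] >= ds) & (d["pos"] < de)]
            if in_anchor.empty:
                continue
            tss_hits = tssf[
                (tssf["chrom"] == gc)
                & (tssf["tss_start"] < ge)
                & (tssf["tss_end"] > gs)
            ]
            for g in tss_hits.itertuples(index=False):
                if g.gene_id not in expression.index:
                    continue
                expr = [float(expression.at[g.gene_id, c]) for c in conditions]
                for h in in_anchor.itertuples(index=False):
                    meth = [getattr(h, c) for c in conditions]
                    r = correlate_meth_expr(meth, expr)
                    rows.append(
                        {
                            "chrom": h.chrom,
                            "pos": h.pos,
                            "gene_id": g.gene_id,
                            "pair_id": pair.pair_id,
                            "r": r,
                            "strong": bool(abs(r) >= r_threshold)
                            if not np.isnan(r)
                            else False,
                        }
                    )
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "gene_id", "pair_id", "r", "strong"]
    )
    return out.drop_duplicates(["chrom", "pos", "gene_id", "pair_id"]).reset_index(
        drop=True
    )
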