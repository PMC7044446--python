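"""Readers, writers and basic transforms for CpG call tables and annotations.

File dialects
-------------
CpG call table : 5 tab-separated columns, no header:
    chrom  pos0  pos1(=pos0+1)  coverage  meth_calls
Coordinates are 0-based half-open throughout (BED-compatible); ``pos0`` is
the position of the C of the CpG.

Features   : BED3+ (chrom, start, end[, name]).
Genes      : BED6  (chrom, start, end, gene_id, score, strand).
Expression : TSV with header: gene_id plus one column per condition.
Interactions : BEDPE (chromA startA endA chromB startB endB [name]).
Occupancy  : bedGraph (chrom start end value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpGParseError",
    "CpGTable",
    "CpGValidationError",
    "FeatureSet",
    "combine_technical_replicates",
    "estimate_nonconversion",
    "filter_by_coverage",
    "read_bed",
    "read_bedgraph",
    "read_bedpe",
    "read_cpg_table",
    "read_expression",
    "read_genes",
    "write_bedgraph_rates",
    "write_cpg_table",
]

CPG_COLUMNS = ["chrom", "pos", "coverage", "meth_calls"]


class CpGParseError(ValueError):
    """A CpG call table line could not be parsed."""


class CpGValidationError(ValueError):
    """A CpG record violates an invariant (e.g. meth_calls > coverage)."""


@dataclass
class CpGTable:
    """Per-sample CpG methylation calls, sorted by (chrom, pos), unique positions.

    ``data`` has columns chrom (str), pos (int, 0-based C position),
    coverage (int >= 0), meth_calls (int >= 0, <= coverage).
    """

    sample_id: str
    condition: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in CPG_COLUMNS if c not in df.columns]
        if missing:
            raise CpGValidationError(f"CpGTable missing columns: {missing}")
        df = df[CPG_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["coverage"] = df["coverage"].astype(np.int64)
        df["meth_calls"] = df["meth_calls"].astype(np.int64)
        if (df["coverage"] < 0).any() or (df["meth_calls"] < 0).any():
            raise CpGValidationError("negative coverage or meth_calls")
        bad = df["meth_calls"] > df["coverage"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CpGValidationError(
                f"meth_calls > coverage at {df.at[i, 'chrom']}:{df.at[i, 'pos']}"
            )
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise CpGValidationError("duplicate (chrom, pos) in CpGTable")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rates(self) -> pd.Series:
        """Methylation rate per CpG (NaN where coverage is 0)."""
        cov = self.data["coverage"].to_numpy(dtype=float)
        meth = self.data["meth_calls"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(cov > 0, meth / np.where(cov > 0, cov, 1), np.nan)
        return pd.Series(r, index=self.data.index, name="rate")


def read_cpg_table(path, sample_id: str, condition: str) -> CpGTable:
    """Read a 5-column CpG call table; duplicate positions have counts summed.

    Raises :class:`CpGParseError` with a line number on malformed input and
    :class:`CpGValidationError` when meth_calls exceeds coverage.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "coverage", "meth_calls"],
            dtype={"chrom": str},
            comment="#",
        )
        for col in ("start", "end", "coverage", "meth_calls"):
            df[col] = df[col].astype(np.int64)
    except (ValueError, TypeError):
        _locate_bad_line(path)
        raise  # pragma: no cover - _locate_bad_line always raises
    if ((df["end"] - df["start"]) != 1).any():
        i = int(np.flatnonzero((df["end"] - df["start"]).to_numpy() != 1)[0])
        raise CpGParseError(f"{path}: line {i + 1}: end != start + 1")
    bad = df["meth_calls"] > df["coverage"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CpGValidationError(f"{path}: line {i + 1}: meth_calls > coverage")
    df = df.rename(columns={"start": "pos"})[CPG_COLUMNS]
    # duplicate call lines for one position are merged by summing the evidence
    df = df.groupby(["chrom", "pos"], as_index=False, sort=True).sum()
    return CpGTable(sample_id=sample_id, condition=condition, data=df)


def _locate_bad_line(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise CpGParseError(
                    f"{path}: line {lineno}: expected 5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                int(parts[1]), int(parts[2]), int(parts[3]), int(parts[4])
            except ValueError:
                raise CpGParseError(
                    f"{path}: line {lineno}: non-integer field in {parts[1:]!r}"
                ) from None
    raise CpGParseError(f"{path}: malformed input")


def write_cpg_table(table: CpGTable, path) -> None:
    """Write the 5-column dialect read by :func:`read_cpg_table`."""
    df = table.data
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "coverage": df["coverage"],
            "meth_calls": df["meth_calls"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph_rates(table: CpGTable, path) -> None:
    """Export per-CpG methylation rates as 4-column bedGraph (coverage>0 only)."""
    df = table.data[table.data["coverage"] > 0]
    rates = df["meth_calls"] / df["coverage"]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "value": rates.round(6),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def combine_technical_replicates(tables: list[CpGTable]) -> CpGTable:
    """Sum coverage and methylated calls per position across technical replicates.

    Positions absent from a replicate contribute zero counts. All inputs must
    share sample_id and condition; count summation (rather than rate
    averaging) preserves the binomial evidence for downstream exact testing.
    """
    if not tables:
        raise ValueError("no tables to combine")
    ids = {t.sample_id for t in tables}
    conds = {t.condition for t in tables}
    if len(ids) > 1:
        raise ValueError(f"mixed sample_ids in replicate set: {sorted(ids)}")
    if len(conds) > 1:
        raise ValueError(f"mixed conditions in replicate set: {sorted(conds)}")
    cat = pd.concat([t.data for t in tables], ignore_index=True)
    if cat.empty:
        merged = cat
    else:
        merged = cat.groupby(["chrom", "pos"], as_index=False, sort=True)[
            ["coverage", "meth_calls"]
        ].sum()
    return CpGTable(sample_id=tables[0].sample_id, condition=tables[0].condition, data=merged)


def filter_by_coverage(tables: list[CpGTable], min_cov: int = 10) -> list[CpGTable]:
    """Keep only CpGs covered >= ``min_cov`` in *every* table (joint filter).

    Output tables share an identical position index; positions missing from
    any sample are dropped, never imputed.
    """
    if not tables:
        raise ValueError("need at least one table")
    if min_cov < 1:
        raise ValueError(f"min_cov must be >= 1, got {min_cov}")
    keys = None
    for t in tables:
        ok = t.data[t.data["coverage"] >= min_cov]
        idx = pd.MultiIndex.from_frame(ok[["chrom", "pos"]])
        keys = idx if keys is None else keys.intersection(idx)
    out = []
    for t in tables:
        d = t.data.set_index(["chrom", "pos"]).loc[keys].reset_index()
        d = d.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        out.append(CpGTable(sample_id=t.sample_id, condition=t.condition, data=d))
    return out


def estimate_nonconversion(table: CpGTable, control_contig: str = "chrM") -> float:
    """Apparent methylation on an unmethylated control contig.

    The mitochondrial genome is assumed unmethylated, so pooled
    meth_calls / coverage over the contig estimates the bisulfite
    non-conversion rate.
    """
    sub = table.data[table.data["chrom"] == control_contig]
    total_cov = int(sub["coverage"].sum())
    if sub.empty or total_cov == 0:
        raise ValueError(
            f"no control data: contig {control_contig!r} absent or zero coverage"
        )
    return float(sub["meth_calls"].sum() / total_cov)


@dataclass
class FeatureSet:
    """A named class of genomic intervals, 0-based half-open.

    Intervals may overlap within the class; :meth:`merged` collapses them.
    """

    name: str
    intervals: pd.DataFrame = field(repr=False)  # columns chrom, start, end

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        df = df[["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"feature set {self.name!r}: interval with start >= end")
        if (df["start"] < 0).any():
            raise ValueError(f"feature set {self.name!r}: negative start")
        self.intervals = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> pd.DataFrame:
        """Overlap-collapsed intervals (touching intervals are joined)."""
        rows = []
        for chrom, grp in self.intervals.groupby("chrom", sort=True):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def covered_bp(self) -> int:
        m = self.merged()
        if m.empty:
            return 0
        return int((m["end"] - m["start"]).sum())


def read_bed(path, name: str | None = None) -> FeatureSet:
    """Read BED3+ intervals into a :class:`FeatureSet`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    fname = name if name is not None else str(path)
    return FeatureSet(name=fname, intervals=df[["chrom", "start", "end"]])


def read_genes(path) -> pd.DataFrame:
    """Read gene models from BED6; returns gene_id, chrom, start, end, strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand must be '+' or '-'")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: gene with start >= end")
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV (gene_id + one column per condition), indexed by gene."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: expression table needs a 'gene_id' column")
    df = df.set_index("gene_id")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def read_bedpe(path) -> pd.DataFrame:
    """Read interaction anchor pairs (BEDPE)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    df = df.rename(
        columns={
            0: "chromA", 1: "startA", 2: "endA",
            3: "chromB", 4: "startB", 5: "endB",
        }
    )
    out = df[["chromA", "startA", "endA", "chromB", "startB", "endB"]].copy()
    out["chromB"] = out["chromB"].astype(str)
    for side in "AB":
        if (out[f"start{side}"] >= out[f"end{side}"]).any():
            raise ValueError(f"{path}: anchor with start >= end")
    out.insert(0, "pair_id", np.arange(len(out)))
    return out


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph track (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)
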