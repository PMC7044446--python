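"""Synthetic WGBS-like data with planted ground truth.

Generates per-condition, per-replicate CpG call tables with a bimodal
background methylome (a dominant highly-methylated mode above 0.75 and a
small lowly-methylated mode below 0.25, plus a partially-methylated band),
planted differentially methylated positions and multi-CpG blocks, feature
tracks, methylation-coupled expression, occupancy tracks with dips at
hypomethylated planted CpGs, and an unmethylated mitochondrial contig
realizing a configured non-conversion rate.

Counts are binomial given each CpG's true rate; coverage is drawn from a
negative-binomial (overdispersed) model so the joint coverage filter is
exercised realistically. All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from methdiff.meth_io import CpGTable, FeatureSet

__all__ = [
    "GroundTruth",
    "SimulationConfig",
    "background_mixture_cdf",
    "simulate_expression",
    "simulate_features",
    "simulate_methylome",
    "simulate_module_profiles",
    "simulate_occupancy",
]

_HIGH_A, _HIGH_B = 36.0, 4.0   # mean 0.9, mass above 0.75
_LOW_A, _LOW_B = 2.0, 38.0     # mean 0.05, mass below 0.25
_PARTIAL_LO, _PARTIAL_HI = 0.25, 0.75


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 500_000
    n_background_cpgs: int = 2000
    conditions: tuple[str, ...] = ("UN", "RA", "TPA")
    n_replicates: int = 2
    mean_coverage: float = 30.0
    coverage_dispersion: float = 10.0
    # background mixture weights (high, low, partial); must sum to 1
    w_high: float = 0.7
    w_low: float = 0.2
    w_partial: float = 0.1
    # planted multi-CpG blocks
    n_dmrs: int = 0
    dmr_cpgs: tuple[int, int] = (7, 15)
    dmr_delta: float = 0.3
    dmr_base_rate: float = 0.2
    dmr_condition: str = "TPA"
    dmr_hypo_fraction: float = 0.0
    dmr_graded: bool = False  # intermediate rate in the middle condition
    dmr_min_gap: int = 3000
    # planted single-CpG shifts
    n_dmps: int = 0
    dmp_delta: float = 0.2
    dmp_condition: str = "TPA"
    # mitochondrial control
    chrm_cpgs: int = 100
    nonconversion: float = 0.005
    # expression coupling
    n_coupled_genes: int = 0
    n_null_genes: int = 0
    expression_base: float = 50.0
    expression_slope: float = 8.0  # log2 units per unit methylation
    expression_noise_sd: float = 0.0
    # feature tracks
    n_neutral_features: int = 50
    feature_width: int = 1000
    n_enhancers: int = 50
    enhancer_enrichment: float = 10.0
    # occupancy
    occupancy_bin: int = 10
    dip_depth: float = 0.5
    dip_halfwidth: int = 75
    dip_condition: str = "TPA"

    def __post_init__(self) -> None:
        if not np.isclose(self.w_high + self.w_low + self.w_partial, 1.0):
            raise ValueError("mixture weights must sum to 1")
        for w in (self.w_high, self.w_low, self.w_partial):
            if not 0 <= w <= 1:
                raise ValueError("mixture weights must be in [0, 1]")
        if self.dmr_condition not in self.conditions:
            raise ValueError("dmr_condition must be one of conditions")


@dataclass
class GroundTruth:
    """Planted structure matching the emitted tables."""

    cpg_rates: pd.DataFrame = field(repr=False)  # chrom, pos, rate per condition
    dmrs: pd.DataFrame = field(repr=False)  # chrom, start, end, n_cpgs, delta, direction
    dmps: pd.DataFrame = field(repr=False)  # chrom, pos, delta
    couplings: pd.DataFrame | None = None  # gene_id, sign, block
    genes: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None


def background_mixture_cdf(x, config: SimulationConfig) -> np.ndarray:
    """CDF of the configured background methylation-rate mixture."""
    x = np.asarray(x, dtype=float)
    return (
        config.w_high * stats.beta.cdf(x, _HIGH_A, _HIGH_B)
        + config.w_low * stats.beta.cdf(x, _LOW_A, _LOW_B)
        + config.w_partial * stats.uniform.cdf(x, _PARTIAL_LO, _PARTIAL_HI - _PARTIAL_LO)
    )


def _draw_background_rates(rng: np.random.Generator, n: int, cfg: SimulationConfig):
    comp = rng.choice(3, size=n, p=[cfg.w_high, cfg.w_low, cfg.w_partial])
    r = np.empty(n)
    r[comp == 0] = rng.beta(_HIGH_A, _HIGH_B, size=(comp == 0).sum())
    r[comp == 1] = rng.beta(_LOW_A, _LOW_B, size=(comp == 1).sum())
    r[comp == 2] = rng.uniform(_PARTIAL_LO, _PARTIAL_HI, size=(comp == 2).sum())
    return r


def _plant_blocks(rng: np.random.Generator, cfg: SimulationConfig):
    """Choose non-overlapping block positions; returns per-block CpG arrays."""
    blocks = []
    if cfg.n_dmrs == 0:
        return blocks
    per_chrom = [cfg.n_dmrs // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_dmrs % cfg.n_chroms):
        per_chrom[i] += 1
    for ci, n_blocks in enumerate(per_chrom):
        if n_blocks == 0:
            continue
        chrom = f"chr{ci + 1}"
        slot = cfg.chrom_length // n_blocks
        for b in range(n_blocks):
            n_cpgs = int(rng.integers(cfg.dmr_cpgs[0], cfg.dmr_cpgs[1] + 1))
            gaps = rng.integers(30, 121, size=n_cpgs - 1)
            width = int(gaps.sum()) + 1
            lo = b * slot + cfg.dmr_min_gap
            hi = (b + 1) * slot - cfg.dmr_min_gap - width
            if hi <= lo:
                raise ValueError("chromosome too short for the requested blocks")
            start = int(rng.integers(lo, hi))
            pos = start + np.concatenate([[0], np.cumsum(gaps)])
            hypo = rng.random() < cfg.dmr_hypo_fraction
            blocks.append({"chrom": chrom, "pos": pos, "hypo": hypo})
    return blocks


def _block_rates(cfg: SimulationConfig, hypo: bool) -> dict[str, float]:
    base = cfg.dmr_base_rate
    shifted = base + cfg.dmr_delta
    rates = {}
    n = len(cfg.conditions)
    target_i = cfg.conditions.index(cfg.dmr_condition)
    for i, cond in enumerate(cfg.conditions):
        if cfg.dmr_graded and n > 2:
            frac = min(i, target_i) / target_i if target_i > 0 else float(i == target_i)
            level = base + cfg.dmr_delta * (frac if i <= target_i else 1.0)
        else:
            level = shifted if i == target_i else base
        rates[cond] = (base + shifted) - level if hypo else level
    return rates


def simulate_methylome(config: SimulationConfig):
    """Generate per-condition x replicate call tables plus ground truth.

    Returns ``(tables, truth)`` where ``tables`` is a list of
    :class:`~methdiff.meth_io.CpGTable` (one per condition x replicate; the
    two technical replicates of a sample are emitted pre-combined as
    independent draws).
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])
    blocks = _plant_blocks(rng, cfg)

    # background positions, excluding a buffer around planted blocks
    frames = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n_bg = cfg.n_background_cpgs // cfg.n_chroms
        pos = np.sort(
            rng.choice(cfg.chrom_length, size=min(n_bg, cfg.chrom_length), replace=False)
        )
        for blk in blocks:
            if blk["chrom"] != chrom:
                continue
            lo, hi = blk["pos"][0] - 500, blk["pos"][-1] + 500
            pos = pos[(pos < lo) | (pos > hi)]
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    bg = pd.concat(frames, ignore_index=True)
    bg_rates = _draw_background_rates(rng, len(bg), cfg)
    rate_cols = {c: bg_rates.copy() for c in cfg.conditions}

    # planted single-CpG shifts on background CpGs
    dmp_rows = []
    if cfg.n_dmps > 0:
        cand = np.flatnonzero(bg_rates + cfg.dmp_delta <= 1.0)
        pick = rng.choice(cand, size=min(cfg.n_dmps, len(cand)), replace=False)
        for i in pick:
            rate_cols[cfg.dmp_condition][i] = bg_rates[i] + cfg.dmp_delta
            dmp_rows.append(
                (bg.at[i, "chrom"], int(bg.at[i, "pos"]), cfg.dmp_delta)
            )
    truth_dmps = pd.DataFrame(dmp_rows, columns=["chrom", "pos", "delta"])

    # planted blocks
    blk_frames, dmr_rows = [], []
    for blk in blocks:
        rates = _block_rates(cfg, blk["hypo"])
        f = pd.DataFrame({"chrom": blk["chrom"], "pos": blk["pos"]})
        for c in cfg.conditions:
            f[c] = rates[c]
        blk_frames.append(f)
        ref = cfg.conditions[0]
        delta = rates[cfg.dmr_condition] - rates[ref]
        dmr_rows.append(
            (
                blk["chrom"], int(blk["pos"][0]), int(blk["pos"][-1] + 1),
                len(blk["pos"]), delta, "hypo" if delta < 0 else "hyper",
            )
        )
    truth_dmrs = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "n_cpgs", "delta", "direction"]
    )

    bg_full = bg.copy()
    for c in cfg.conditions:
        bg_full[c] = rate_cols[c]
    all_rates = pd.concat([bg_full] + blk_frames, ignore_index=True)

    # mitochondrial control contig
    if cfg.chrm_cpgs > 0:
        chrm = pd.DataFrame(
            {"chrom": "chrM", "pos": np.arange(cfg.chrm_cpgs) * 50 + 10}
        )
        for c in cfg.conditions:
            chrm[c] = cfg.nonconversion
        all_rates = pd.concat([all_rates, chrm], ignore_index=True)

    all_rates = all_rates.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )

    # draw counts per condition x replicate
    p_nb = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.mean_coverage)
    tables = []
    n = len(all_rates)
    for cond in cfg.conditions:
        true_rate = all_rates[cond].to_numpy()
        for rep in range(1, cfg.n_replicates + 1):
            cov = rng.negative_binomial(cfg.coverage_dispersion, p_nb, size=n)
            meth = rng.binomial(cov, true_rate)
            tables.append(
                CpGTable(
                    sample_id=f"{cond}_rep{rep}",
                    condition=cond,
                    data=pd.DataFrame(
                        {
                            "chrom": all_rates["chrom"],
                            "pos": all_rates["pos"],
                            "coverage": cov,
                            "meth_calls": meth,
                        }
                    ),
                )
            )
    truth = GroundTruth(cpg_rates=all_rates, dmrs=truth_dmrs, dmps=truth_dmps)
    return tables, truth


def simulate_features(config: SimulationConfig, truth: GroundTruth):
    """Emit an "enhancer" class enriched over planted blocks plus a neutral class.

    With enrichment factor f, each enhancer covers a random planted block
    with probability min(1, f * total_block_bp / genome_bp) and is placed
    uniformly otherwise; f = 1 reproduces uniform placement in expectation.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    genome_bp = cfg.n_chroms * cfg.chrom_length
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]

    def uniform_interval(width):
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        start = int(rng.integers(0, cfg.chrom_length - width))
        return chrom, start, start + width

    rows = []
    block_bp = 0
    blocks = truth.dmrs
    if len(blocks):
        block_bp = int((blocks["end"] - blocks["start"]).sum())
    p_block = min(1.0, cfg.enhancer_enrichment * block_bp / genome_bp) if block_bp else 0.0
    for _ in range(cfg.n_enhancers):
        if rng.random() < p_block:
            b = blocks.iloc[int(rng.integers(len(blocks)))]
            mid = int((b["start"] + b["end"]) // 2)
            start = max(0, mid - cfg.feature_width // 2)
            rows.append((b["chrom"], start, start + cfg.feature_width))
        else:
            rows.append(uniform_interval(cfg.feature_width))
    enhancers = FeatureSet(
        name="enhancer", intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"])
    )
    neutral_rows = [uniform_interval(cfg.feature_width) for _ in range(cfg.n_neutral_features)]
    neutral = FeatureSet(
        name="neutral",
        intervals=pd.DataFrame(neutral_rows, columns=["chrom", "start", "end"]),
    )
    return {"enhancer": enhancers, "neutral": neutral}


def simulate_expression(config: SimulationConfig, truth: GroundTruth):
    """Couple gene expression to planted-block methylation.

    Coupled gene g (sign s) gets, per condition c,
        expr = base * 2 ** (s * slope * (meth_c - mean(meth))) * noise
    where meth_c is the block's true rate in condition c — a monotone
    function of methylation whose direction is the planted sign. Null genes
    get condition-independent expression (times noise). Updates ``truth``
    in place with the gene models, expression table and couplings.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 2])
    if cfg.n_coupled_genes > 0 and truth.dmrs.empty:
        raise ValueError("coupled genes need planted blocks")
    gene_rows, expr_rows, coupling_rows = [], [], []
    for gi in range(cfg.n_coupled_genes):
        b = truth.dmrs.iloc[gi % len(truth.dmrs)]
        gene_id = f"gene_cpl_{gi}"
        start = int(b["end"]) + 500
        gene_rows.append((gene_id, b["chrom"], start, start + 2000, "+"))
        block_cpgs = truth.cpg_rates[
            (truth.cpg_rates["chrom"] == b["chrom"])
            & (truth.cpg_rates["pos"] >= b["start"])
            & (truth.cpg_rates["pos"] < b["end"])
        ]
        meth = np.array([block_cpgs[c].mean() for c in cfg.conditions])
        sign = 1 if gi % 2 == 0 else -1
        noise = np.exp(rng.normal(0.0, cfg.expression_noise_sd, size=len(meth)))
        expr = cfg.expression_base * 2.0 ** (
            sign * cfg.expression_slope * (meth - meth.mean())
        ) * noise
        expr_rows.append([gene_id, *expr])
        coupling_rows.append((gene_id, sign, int(gi % len(truth.dmrs))))
    for gi in range(cfg.n_null_genes):
        gene_id = f"gene_null_{gi}"
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        start = int(rng.integers(0, cfg.chrom_length - 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((gene_id, chrom, start, start + 2000, strand))
        noise = np.exp(
            rng.normal(0.0, cfg.expression_noise_sd, size=len(cfg.conditions))
        )
        expr_rows.append([gene_id, *(cfg.expression_base * noise)])
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    expression = pd.DataFrame(
        expr_rows, columns=["gene_id", *cfg.conditions]
    ).set_index("gene_id")
    truth.genes = genes
    truth.expression = expression
    truth.couplings = pd.DataFrame(
        coupling_rows, columns=["gene_id", "sign", "block"]
    )
    return genes, expression


def simulate_occupancy(config: SimulationConfig, truth: GroundTruth):
    """Per-condition bedGraph occupancy: baseline 1.0 with dips at
    hypomethylated planted CpGs in the dip condition.

    Dip anchors are the CpGs of hypo-direction planted blocks plus planted
    DMPs with negative delta; bins overlapping anchor +/- dip_halfwidth get
    value 1 - dip_depth. Bins tile each chromosome without overlap.
    """
    cfg = config
    anchors = []
    hypo_blocks = truth.dmrs[truth.dmrs["direction"] == "hypo"]
    for b in hypo_blocks.itertuples(index=False):
        cp = truth.cpg_rates[
            (truth.cpg_rates["chrom"] == b.chrom)
            & (truth.cpg_rates["pos"] >= b.start)
            & (truth.cpg_rates["pos"] < b.end)
        ]
        anchors.extend(zip(cp["chrom"], cp["pos"]))
    if truth.dmps is not None and len(truth.dmps):
        neg = truth.dmps[truth.dmps["delta"] < 0]
        anchors.extend(zip(neg["chrom"], neg["pos"]))

    tracks = {}
    for cond in cfg.conditions:
        frames = []
        for ci in range(cfg.n_chroms):
            chrom = f"chr{ci + 1}"
            starts = np.arange(0, cfg.chrom_length, cfg.occupancy_bin)
            ends = np.minimum(starts + cfg.occupancy_bin, cfg.chrom_length)
            values = np.ones(len(starts))
            if cond == cfg.dip_condition:
                for (achrom, apos) in anchors:
                    if achrom != chrom:
                        continue
                    lo, hi = apos - cfg.dip_halfwidth, apos + cfg.dip_halfwidth
                    hit = (ends > lo) & (starts <= hi)
                    values[hit] = 1.0 - cfg.dip_depth
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": values}
                )
            )
        tracks[cond] = pd.concat(frames, ignore_index=True)
    return tracks


def write_dataset(config: SimulationConfig, outdir):
    """Write a full synthetic dataset and return a ready pipeline config.

    Emits call tables, feature BEDs, gene models, expression, occupancy
    bedGraphs and the ground-truth tables into ``outdir``, plus a
    ``pipeline_config.yaml``; returns ``(pipeline_config, truth)``.
    """
    from dataclasses import asdict
    from pathlib import Path

    import yaml

    from methdiff.meth_io import write_cpg_table
    from methdiff.pipeline import PipelineConfig

    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_methylome(cfg)
    samples = []
    for t in tables:
        path = outdir / f"calls_{t.sample_id}.tsv"
        write_cpg_table(t, path)
        samples.append(
            {"path": str(path), "sample_id": t.sample_id, "condition": t.condition}
        )
    features = simulate_features(cfg, truth)
    feature_paths = {}
    for name, fs in features.items():
        path = outdir / f"features_{name}.bed"
        fs.intervals.to_csv(path, sep="\t", header=False, index=False)
        feature_paths[name] = str(path)
    integrate = cfg.n_coupled_genes + cfg.n_null_genes > 0
    genes_path = expr_path = None
    if integrate:
        genes, expression = simulate_expression(cfg, truth)
        genes_path = outdir / "genes.bed"
        bed6 = genes.assign(score=0)[
            ["chrom", "start", "end", "gene_id", "score", "strand"]
        ]
        bed6.to_csv(genes_path, sep="\t", header=False, index=False)
        expr_path = outdir / "expression.tsv"
        expression.reset_index().to_csv(expr_path, sep="\t", index=False)
    occ_paths = {}
    for cond, track in simulate_occupancy(cfg, truth).items():
        path = outdir / f"occupancy_{cond}.bedGraph"
        track.to_csv(path, sep="\t", header=False, index=False)
        occ_paths[cond] = str(path)
    truth.dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    truth.dmps.to_csv(outdir / "truth_dmps.tsv", sep="\t", index=False)
    if truth.couplings is not None:
        truth.couplings.to_csv(outdir / "truth_couplings.tsv", sep="\t", index=False)
    pipeline_cfg = PipelineConfig(
        samples=samples,
        conditions=list(cfg.conditions),
        genome_size=cfg.n_chroms * cfg.chrom_length,
        features=feature_paths,
        genes=str(genes_path) if genes_path else None,
        expression=str(expr_path) if expr_path else None,
        occupancy=occ_paths,
        integrate=integrate,
        seed=cfg.seed,
    )
    with open(outdir / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(pipeline_cfg), fh, sort_keys=True)
    return pipeline_cfg, truth


def simulate_module_profiles(
    k: int = 12,
    n_per: int = 10,
    n_conditions: int = 3,
    separation: float = 0.3,
    jitter: float = 0.001,
    seed: int = 0,
):
    """``k`` well-separated rate archetypes with ``n_per`` jittered copies each.

    Archetypes are drawn in [0.05, 0.95]^n_conditions with pairwise
    Euclidean distance >= separation (rejection sampling). Returns
    ``(profiles, labels)`` where labels give each row's archetype index.
    """
    rng = np.random.default_rng([seed, 4])
    archetypes = []
    attempts = 0
    while len(archetypes) < k:
        cand = rng.uniform(0.05, 0.95, size=n_conditions)
        if all(np.linalg.norm(cand - a) >= separation for a in archetypes):
            archetypes.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place archetypes; lower separation")
    rows, labels = [], []
    for i, a in enumerate(archetypes):
        pts = np.clip(a + rng.normal(0, jitter, size=(n_per, n_conditions)), 0, 1)
        rows.append(pts)
        labels.extend([i] * n_per)
    profiles = pd.DataFrame(
        np.vstack(rows), columns=[f"cond{j}" for j in range(n_conditions)]
    )
    return profiles, np.asarray(labels)
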