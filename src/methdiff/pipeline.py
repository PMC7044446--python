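"""Configuration-driven orchestration of the full analysis.

Stage order: joint coverage filter -> per-comparison DMP calling -> DMP
union -> DMR calling -> module clustering -> feature enrichment ->
expression integration -> occupancy profiles. Each stage's output is
written before the next stage runs, every effective parameter lands in the
machine-readable run log, and re-running an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from methdiff import dmp as dmp_mod
from methdiff import dmr as dmr_mod
from methdiff import meth_io
from methdiff.enrichment import dmp_feature_enrichment, module_feature_enrichment
from methdiff.integration import correlation_histogram, link_distal, select_candidates
from methdiff.modules import cluster_dmps, occupancy_profile, summarize_modules

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("methdiff")

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All inputs and stage parameters; defaults match the reference analysis."""

    # input manifest: list of {path, sample_id, condition}
    samples: list[dict] = field(default_factory=list)
    conditions: list[str] = field(default_factory=lambda: ["UN", "RA", "TPA"])
    comparisons: list[list[str]] | None = None  # default: all vs first + last pair
    min_cov: int = 10
    alpha: float = 0.05
    window_cpgs: int = 3
    max_span: int = 2000
    min_density: float = 3.0
    min_windows: int = 3
    k_modules: int = 12
    min_delta: float = 0.2
    min_lfc: float = 1.5
    flank: int = 1000
    r_threshold: float = 0.7
    genome_size: int | None = None
    features: dict[str, str] = field(default_factory=dict)  # name -> BED path
    genes: str | None = None  # BED6 path
    expression: str | None = None  # TSV path
    interactions: str | None = None  # BEDPE path
    occupancy: dict[str, str] = field(default_factory=dict)  # condition -> bedGraph
    tfbs_feature: str | None = None  # key into features used as the TFBS class
    integrate: bool = False
    control_contig: str = "chrM"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def effective_comparisons(self) -> list[tuple[str, str]]:
        if self.comparisons:
            return [tuple(c) for c in self.comparisons]
        conds = self.conditions
        pairs = [(conds[0], c) for c in conds[1:]]
        if len(conds) > 2:
            pairs.append((conds[-1], conds[1]))
        return pairs


def _write(df: pd.DataFrame, path: Path, header_note: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _dmp_bed(dmps: pd.DataFrame, name: str) -> pd.DataFrame:
    with np.errstate(divide="ignore"):
        score = -np.log10(np.maximum(dmps["p_value"].to_numpy(), 1e-300))
    return pd.DataFrame(
        {
            "chrom": dmps["chrom"],
            "start": dmps["pos"],
            "end": dmps["pos"] + 1,
            "name": name,
            "score": np.round(score, 4),
            "strand": ".",
            "rate_a": dmps["rate_a"],
            "rate_b": dmps["rate_b"],
            "delta": dmps["delta"],
            "direction": dmps["direction"],
        }
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all configured stages; returns the run log dictionary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"parameters": asdict(config), "stages": []}
    stage = "load"
    try:
        tables = [
            meth_io.read_cpg_table(s["path"], s["sample_id"], s["condition"])
            for s in config.samples
        ]
        if not tables:
            raise PipelineError("no input samples configured")
        log["stages"].append({"stage": stage, "n_samples": len(tables)})

        stage = "nonconversion"
        nonconv = {}
        for t in tables:
            try:
                nonconv[t.sample_id] = estimate = meth_io.estimate_nonconversion(
                    t, config.control_contig
                )
                logger.info("non-conversion %s: %.4f", t.sample_id, estimate)
            except ValueError:
                nonconv[t.sample_id] = None
        log["stages"].append({"stage": stage, "nonconversion": nonconv})

        stage = "filter"
        autosomal = [
            meth_io.CpGTable(
                t.sample_id,
                t.condition,
                t.data[t.data["chrom"] != config.control_contig],
            )
            for t in tables
        ]
        filtered = meth_io.filter_by_coverage(autosomal, config.min_cov)
        n_kept = len(filtered[0])
        log["stages"].append({"stage": stage, "n_cpgs_kept": n_kept})

        stage = "pool"
        pooled = {
            c: dmp_mod.pool_condition_counts(filtered, c) for c in config.conditions
        }
        rates = filtered[0].data[["chrom", "pos"]].copy()
        for c in config.conditions:
            rates[c] = pooled[c]["meth_calls"] / pooled[c]["coverage"]

        stage = "dmp"
        dmp_sets: dict[str, pd.DataFrame] = {}
        for (a, b) in config.effective_comparisons():
            name = f"{b}_vs_{a}"
            dmps = dmp_mod.fisher_dmp(pooled[a], pooled[b], config.alpha)
            dmp_sets[name] = dmps
            _write(
                _dmp_bed(dmps, name),
                out / f"dmps_{name}.bed.tsv",
                f"DMPs {name} alpha={config.alpha} min_cov={config.min_cov}",
            )
        log["stages"].append(
            {"stage": stage, "n_dmps": {k: len(v) for k, v in dmp_sets.items()}}
        )

        stage = "union"
        union = dmp_mod.union_dmps(dmp_sets)
        _write(union, out / "dmps_union.tsv", "union of per-comparison DMPs")
        log["stages"].append({"stage": stage, "n_unique_dmps": len(union)})

        stage = "dmr"
        dmr_counts = {}
        for (a, b) in config.effective_comparisons():
            name = f"{b}_vs_{a}"
            dmrs = dmr_mod.call_dmrs(
                pooled[a],
                pooled[b],
                alpha=config.alpha,
                window_cpgs=config.window_cpgs,
                max_span=config.max_span,
                min_density=config.min_density,
                min_windows=config.min_windows,
            )
            dmr_counts[name] = len(dmrs)
            _write(
                dmrs,
                out / f"dmrs_{name}.tsv",
                f"DMRs {name} alpha={config.alpha} max_span={config.max_span} "
                f"min_density={config.min_density} min_windows={config.min_windows}",
            )
        log["stages"].append({"stage": stage, "n_dmrs": dmr_counts})

        stage = "modules"
        module_table = pd.DataFrame()
        if len(union) >= config.k_modules:
            profiles = union.merge(rates, on=["chrom", "pos"], how="left")
            labels = cluster_dmps(profiles[config.conditions], config.k_modules)
            module_table = profiles[["chrom", "pos", *config.conditions]].copy()
            module_table.insert(2, "module", labels.to_numpy())
            _write(
                module_table,
                out / "modules.tsv",
                f"DMP modules k={config.k_modules} (complete linkage, Euclidean)",
            )
            summary = summarize_modules(labels, profiles[config.conditions])
            _write(summary, out / "module_summary.tsv", "per-module condition means")
            log["stages"].append(
                {"stage": stage, "k": config.k_modules, "n_dmps": len(module_table)}
            )
        else:
            log["stages"].append({"stage": stage, "skipped": "fewer DMPs than k"})

        stage = "enrichment"
        if config.features:
            feature_sets = {
                name: meth_io.read_bed(path, name)
                for name, path in sorted(config.features.items())
            }
            genome_size = config.genome_size
            if genome_size is None:
                raise PipelineError("enrichment needs genome_size in the config")
            rows = []
            for name, dmps in sorted(dmp_sets.items()):
                for direction in ("hyper", "hypo"):
                    sub = dmps[dmps["direction"] == direction]
                    for fs in feature_sets.values():
                        if len(dmps) == 0 or len(sub) == 0:
                            continue
                        res = dmp_feature_enrichment(
                            sub, len(dmps), fs, genome_size,
                            subject=f"{name}:{direction}",
                        )
                        rows.append(
                            {
                                "subject": res.subject,
                                "feature": res.feature,
                                "observed": res.observed,
                                "observed_fraction": res.observed_fraction,
                                "expected_fraction": res.expected_fraction,
                                "ratio": res.ratio,
                                "log2_ratio": res.log2_ratio,
                            }
                        )
            _write(
                pd.DataFrame(rows),
                out / "dmp_enrichment.tsv",
                f"DMP subset enrichment genome_size={genome_size}",
            )
            if not module_table.empty:
                menr = module_feature_enrichment(
                    module_table[["chrom", "pos", "module"]],
                    list(feature_sets.values()),
                )
                _write(menr, out / "module_enrichment.tsv", "module enrichment")
            log["stages"].append(
                {"stage": stage, "features": sorted(feature_sets)}
            )

        stage = "integration"
        if config.integrate:
            if not config.genes or not config.expression:
                raise PipelineError(
                    "integration enabled but genes/expression tables missing"
                )
            genes = meth_io.read_genes(config.genes)
            expression = meth_io.read_expression(config.expression)
            tfbs = None
            if config.tfbs_feature:
                tfbs = meth_io.read_bed(
                    config.features[config.tfbs_feature], config.tfbs_feature
                )
            for (a, b) in config.effective_comparisons():
                name = f"{b}_vs_{a}"
                cand, assoc = select_candidates(
                    dmp_sets[name], rates, genes, expression, a, b,
                    tfbs=tfbs,
                    min_delta=config.min_delta,
                    min_lfc=config.min_lfc,
                    conditions=config.conditions,
                )
                _write(
                    cand,
                    out / f"candidates_{name}.tsv",
                    f"candidate genes {name} min_delta={config.min_delta} "
                    f"min_lfc={config.min_lfc}",
                )
                _write(assoc, out / f"gene_dmp_pairs_{name}.tsv", f"pairs {name}")
                counts, edges, n_missing = correlation_histogram(cand["r"])
                hist = pd.DataFrame(
                    {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
                )
                _write(
                    hist,
                    out / f"correlation_hist_{name}.tsv",
                    f"r histogram {name} n_missing={n_missing}",
                )
            if config.interactions:
                inter = meth_io.read_bedpe(config.interactions)
                all_dmps = pd.concat(dmp_sets.values(), ignore_index=True)
                all_dmps = all_dmps.drop_duplicates(["chrom", "pos"])
                links = link_distal(
                    all_dmps, rates, inter, genes, expression,
                    conditions=config.conditions,
                    r_threshold=config.r_threshold,
                )
                _write(links, out / "distal_links.tsv", "interaction-anchored links")
            log["stages"].append({"stage": stage, "done": True})

        stage = "profiles"
        if config.occupancy and not module_table.empty:
            for cond, path in sorted(config.occupancy.items()):
                track = meth_io.read_bedgraph(path)
                for m in sorted(module_table["module"].unique()):
                    anchors = module_table.loc[
                        module_table["module"] == m, ["chrom", "pos"]
                    ]
                    prof = occupancy_profile(track, anchors, config.flank)
                    _write(
                        prof.to_frame(),
                        out / f"occupancy_{cond}_M{m}.tsv",
                        f"occupancy {cond} module M{m} flank={config.flank} "
                        f"n_anchors={prof.n_anchors}",
                    )
            log["stages"].append({"stage": stage, "done": True})
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return log
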