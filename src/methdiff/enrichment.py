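"""Genomic-feature enrichment of DMP subsets and of DMP modules.

Both enrichments are descriptive fold ratios (observed fraction divided by
expected fraction); no significance test is attached.

* DMP-subset enrichment compares the fraction of a comparison's DMPs (the
  hyper- or hypo-methylated subset) falling inside a feature class against
  the fraction of the genome the feature covers. The denominator
  ``data_size`` is the *total* DMP count of the comparison, not the subset
  size.
* Module enrichment is count-based: the fraction of a feature's DMPs that
  belong to a module, divided by the module's share of all DMPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methdiff.meth_io import FeatureSet

__all__ = [
    "EnrichmentResult",
    "dmp_feature_enrichment",
    "module_feature_enrichment",
    "overlap_count",
]


@dataclass
class EnrichmentResult:
    subject: str
    feature: str
    observed: int
    observed_fraction: float
    expected_fraction: float
    ratio: float

    @property
    def log2_ratio(self) -> float:
        """log2 of the ratio; NaN when the ratio is 0 or undefined."""
        if self.ratio > 0:
            return float(np.log2(self.ratio))
        return float("nan")


def overlap_count(points: pd.DataFrame, features: FeatureSet) -> int:
    """Number of points (chrom, pos) inside any interval of the feature class.

    Intervals are half-open [start, end); each point counts once even when
    intervals overlap.
    """
    return int(_membership(points, features).sum())


def _membership(points: pd.DataFrame, features: FeatureSet) -> np.ndarray:
    """Boolean mask: point i lies inside some (merged) feature interval."""
    merged = features.merged()
    mask = np.zeros(len(points), dtype=bool)
    pts = points.reset_index(drop=True)
    for chrom, grp in pts.groupby("chrom", sort=False):
        f = merged[merged["chrom"] == chrom]
        if f.empty:
            continue
        starts = f["start"].to_numpy()
        ends = f["end"].to_numpy()
        pos = grp["pos"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos < ends[np.clip(i, 0, len(ends) - 1)])
        mask[grp.index.to_numpy()] = inside
    return mask


def dmp_feature_enrichment(
    dmps: pd.DataFrame,
    data_size: int,
    features: FeatureSet,
    genome_size: int,
    subject: str = "dmps",
) -> EnrichmentResult:
    """Fold enrichment of a DMP subset in a feature class.

    enrichment = (subset DMPs inside feature / data_size)
               / (feature covered bp / genome_size)

    ``data_size`` is the comparison's total DMP count (hyper + hypo), even
    when ``dmps`` is the hyper- or hypo-only subset.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if data_size <= 0:
        raise ValueError("data_size must be > 0")
    covered = features.covered_bp()
    if covered == 0:
        raise ValueError(f"feature class {features.name!r} covers 0 bp")
    observed = overlap_count(dmps[["chrom", "pos"]], features)
    obs_frac = observed / data_size
    exp_frac = covered / genome_size
    return EnrichmentResult(
        subject=subject,
        feature=features.name,
        observed=observed,
        observed_fraction=obs_frac,
        expected_fraction=exp_frac,
        ratio=obs_frac / exp_frac,
    )


def module_feature_enrichment(
    module_dmps: pd.DataFrame,
    features: list[FeatureSet],
) -> pd.DataFrame:
    """Count-based enrichment of every module in every feature class.

    ``module_dmps`` has columns chrom, pos, module (every DMP assigned).
    For module m and feature f:

        enrichment(m, f) = (mod_feature / feature_size)
                         / (module_size / total_modules)

    where mod_feature = DMPs of m inside f, feature_size = DMPs of any
    module inside f, module_size = DMPs in m, total_modules = all DMPs.
    Features containing no DMP yield NaN ratios rather than an error.
    """
    if module_dmps["module"].isna().any():
        raise ValueError("every DMP must carry a module label")
    total = len(module_dmps)
    if total == 0:
        raise ValueError("no DMPs")
    labels = np.sort(module_dmps["module"].unique())
    rows = []
    for fs in features:
        inside = _membership(module_dmps[["chrom", "pos"]], fs)
        feature_size = int(inside.sum())
        for m in labels:
            sel = (module_dmps["module"] == m).to_numpy()
            module_size = int(sel.sum())
            mod_feature = int((inside & sel).sum())
            if feature_size == 0:
                ratio = np.nan
            else:
                ratio = (mod_feature / feature_size) / (module_size / total)
            rows.append(
                {
                    "module": m,
                    "feature": fs.name,
                    "mod_feature": mod_feature,
                    "feature_size": feature_size,
                    "module_size": module_size,
                    "total_modules": total,
                    "ratio": ratio,
                    "log2_ratio": np.log2(ratio) if ratio and ratio > 0 else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    # conservation checks: module counts partition the feature counts
    for fs in features:
        sub = out[out["feature"] == fs.name]
        assert int(sub["mod_feature"].sum()) == int(sub["feature_size"].iloc[0])
    per_module = out.drop_duplicates("module")
    assert int(per_module["module_size"].sum()) == total
    return out
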