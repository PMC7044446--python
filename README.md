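# methdiff

Differential DNA-methylation analysis of whole-genome bisulfite sequencing
(WGBS) CpG call tables across multiple cell states, built around the
workflow used for chemically induced myeloid differentiation experiments:

- **meth_io** — readers/writers for CpG call tables (5-column TSV), BED
  features, BED6 gene models, expression TSVs, BEDPE interaction pairs and
  bedGraph occupancy tracks; technical-replicate combination by count
  summation; joint coverage filtering (CpGs kept only with ≥10× coverage in
  *every* sample); bisulfite non-conversion estimation from chrM.
- **dmp** — per-CpG two-sided Fisher exact testing of pooled condition
  counts at α = 0.05 (optional Benjamini–Hochberg mode), hyper/hypo
  classification by rate difference, union over pairwise comparisons, and
  sample-level PCA (samples as observations, mean-centered CpG rates).
- **dmr** — five-step sliding-window DMR extraction: overlapping 3-CpG
  windows (step 1 CpG, max span 2 kb) with averaged counts, per-window
  Fisher test, merging of consecutive same-direction significant windows,
  second-pass Fisher on summed region counts, and the density (≥3 CpGs/kb)
  plus minimum-window (≥3 windows ⇒ ≥5 CpGs) filters.
- **modules** — hierarchical clustering of DMP methylation profiles
  (complete linkage, Euclidean distance, tree cut at k = 12 "modules") and
  average nucleosome-occupancy profiles ±1 kb around module CpGs.
- **enrichment** — descriptive fold-enrichment of DMP subsets against
  genome-fraction expectations and count-based module × feature enrichment
  with built-in conservation checks.
- **integration** — TSS regions (−2 kb/+1 kb, strand-aware with a
  strand-naive mode), candidate genes (|log2FC| ≥ 1.5 with a TSS DMP of
  |Δ| ≥ 0.2 inside a TFBS), per-gene Pearson correlation of TSS
  methylation with expression across conditions, correlation histograms,
  and distal DMP→gene links through chromatin-interaction anchor pairs.
- **simulate** — synthetic WGBS-like data with planted ground truth:
  bimodal background methylome, planted DMPs/DMR blocks, enriched feature
  tracks, methylation-coupled expression, occupancy dips at hypomethylated
  CpGs, and a chrM contig realizing a configured non-conversion rate.
- **pipeline / cli** — YAML-configured orchestration of all stages with a
  machine-readable run log and deterministic outputs.

## CLI

Generate a synthetic dataset (with ground truth and a ready pipeline
config), then run everything:

```sh
methdiff simulate --out data/ --seed 1 --n-cpgs 2000 --n-dmrs 10
methdiff run-all --config data/pipeline_config.yaml --out results/run
```

Individual stages are also exposed (`methdiff filter|dmp|dmr|nonconversion`),
each taking repeated `--sample PATH:SAMPLE_ID:CONDITION` options, e.g.

```sh
methdiff dmr \
  --sample data/calls_UN_rep1.tsv:UN_rep1:UN \
  --sample data/calls_TPA_rep1.tsv:TPA_rep1:TPA \
  --cond-a UN --cond-b TPA --out dmrs.tsv
```

## File dialects

CpG call tables are 5-column TSV (`chrom  pos0  pos1  coverage
meth_calls`, 0-based half-open, `pos0` = position of the C of the CpG).
Features are BED3+, genes BED6, expression a TSV with a `gene_id` column
plus one column per condition, interactions BEDPE, occupancy bedGraph.
All coordinates are 0-based half-open throughout.

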