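# spcprof

Label-free spectral-count proteome profiling for small multi-cohort
(MudPIT-style) study designs. Starting from per-run protein
identification lists (TSV: accession → spectral count), the package
provides:

- **Identification QC** — per-charge Xcorr / peptide-probability /
  consensus-score PSM filters, target–decoy FDR (decoys/targets), and
  replicate repeatability regression (slope, R²).
- **Cohort profiling** — average spectral counts (aSpC), depth
  normalization (total-count scaling, NSAF), three-way Venn
  partitioning, virtual 2D MW/pI maps with extreme-tail counts, and
  subcellular-location summaries.
- **Dual-index differential analysis** — DAve = 2(X−Y)/(X+Y) and
  DCI = (X+Y)(X−Y)/2 per protein, with a protein called differentially
  expressed when |DAve| ≥ 0.4 **and** |DCI| ≥ 15 (both configurable);
  pairwise cohort comparisons and the distinct DEP union.
- **Discriminant protein selection & clustering** — per-protein one-way
  F-ratio screening (F > 3.4, p < 0.05 defaults, optional gene-level
  collapsing), Mahalanobis-distance cohort assignment under a pooled
  (diagonal or shrunk) covariance, Ward/average hierarchical clustering
  of runs with the AGNES agglomerative coefficient and Newick export.
- **Network mapping & enrichment** — induced PPI subnetworks of DEP/
  selected gene sets over a user-supplied edge list (TSV or SIF), node
  state coloring, and upper-tail hypergeometric term enrichment with
  Benjamini–Hochberg correction (q ≤ 0.001 default).
- **Synthetic data** — a generator for the 19-run / 3-cohort design
  (Wt 1×7, He 2×2+2×1, Ho 2×3 injections) with negative-binomial
  counts, per-subject biological variation, planted fold changes,
  cohort-specific proteins, MW/pI tails, and a ground-truth manifest,
  so every stage is testable offline.

## CLI

All functionality is reachable through the `spcprof` entry point:

```sh
spcprof simulate --seed 1 --n-proteins 1000 --out data/sim      # synthetic dataset
spcprof qc       --dataset data/sim --out qc.tsv                # replicate regressions
spcprof profile  --dataset data/sim --out profile_out           # aSpC, Venn, 2D map
spcprof diff     --dataset data/sim --dave-thr 0.4 --dci-thr 15 --out diff_out
spcprof lda      --dataset data/sim --out lda.tsv               # F-ratio screen
spcprof cluster  --dataset data/sim --out cluster_out           # dendrogram + AC
spcprof network  --edges ppi.tsv --query genes.txt --out sub.tsv
spcprof enrich   --query q.txt --universe u.txt --terms terms.tsv --out enr.tsv
spcprof run      --dataset data/sim --out full_out --seed 1     # end-to-end
spcprof replicate --dataset data/appendix_a --out replication.json
```

Exit codes: 0 success, 2 validation/config error, 3 parse error. The
`run` subcommand also accepts a YAML config (`--config`); flags
override config values, and every output file is stamped with a config
hash and the seed.

### Dataset directory layout

A dataset directory contains one TSV per run plus `manifest.tsv` with
columns `run_id`, `subject_id`, `cohort` (Wt/He/Ho), `replicate_kind`
(technical/biological) and `path`. Run lists carry at least
`accession` and `spc` columns (`gene`, `description`, `mw_kda`, `pi`,
`location` optional); other column names can be remapped via a dialect
mapping. Optional `annotation.tsv` (accession → gene/MW/pI/location)
and `terms.tsv` (gene → term) complete the inputs.

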