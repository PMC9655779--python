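# stress-ccc

Behavioral stratification and single-cell cell-cell communication
analysis for chronic social defeat stress (CSDS) experiments in mice.

After ten days of social defeat, only a fraction of mice develop
lasting social avoidance.  Stratifying defeated animals by their
social interaction (SI) index — time exploring an enclosure holding an
aggressor CD1 mouse over time exploring the same enclosure empty —
separates resilient (R), intermediate (Int) and susceptible (S)
sub-phenotypes, and single-cell RNA-seq of hippocampal tissue can then
ask which cell types respond transcriptionally in which sub-region.
This package implements that analysis chain as a tested, reusable
library for behavioral neuroscientists and computational biologists:

* **behavior** — SI and modified-SI (MSI) indices from raw zone times;
  extreme-animal selection (SI < 0.75 or > 1.15); stratification with
  a univariate 3-component Gaussian mixture fit by EM
  (S < Int < R by component mean) or by fixed thresholds
  (R: SI > 1.15, S: SI < 0.50, Int: 0.50–0.75); PCA with
  correlation-scale loadings; variance-ratio F test; chi-squared
  comparison of phenotype proportions.
* **preprocess** — QC (< 15% mitochondrial counts, 200–2500 detected
  features), log-normalization `ln(1 + 10^4 · count / total)`,
  highly-variable-gene selection, hemisphere pooling, marker dot-plot
  statistics, signature-based cluster annotation.
* **diffexpr** — per-cluster and pooled Wilcoxon rank-sum differential
  expression vs control with the standard single-cell conventions
  (natural-log fold change of pseudocounted means, min.pct 0.1,
  Benjamini–Hochberg FDR; DEG = |logFC| > 0.25 and adj. p < 0.05),
  ΔPCT and marker-panel fold-change summaries.
* **enrichment** — hypergeometric over-representation of DEG lists
  against GMT gene-set collections.
* **ccc** — the ligand–receptor network rule: cell type *x* signals to
  cell type *y* through (L, R) when L is upregulated in *x*, R is
  upregulated in *y*, and (L, R) occurs in a curated reference
  (CellTalkDB-style TSV).  Edge lists, unique-pair counts, adjacency
  and degree summaries.
* **simulate** — synthetic behavioral tables and negative-binomial
  count matrices with planted DEGs and planted communication edges,
  so every downstream claim can be checked against ground truth.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the full synthetic pipeline (simulate → stratify → preprocess →
DE → enrichment → ligand–receptor network):

```bash
stress-ccc run --seed 1 --out results/demo
```

which logs, per stage (numbers for seed 1):

```
stage counts: {'simulate': {'mice': 70, 'cells': 6400, 'genes': 1000, 'lr_pairs': 105},
 'stratify': {'defeated': 58, 'gmm_iterations': 38, 'gmm_converged': True},
 'preprocess': {'cells_in': 6400, 'cells_kept': 6400, 'removed_mito': 0, 'removed_features': 0, 'hvg': 1000},
 'de': {'comparisons': 24, 'filtered_degs': 89},
 'enrich': {'query': 85, 'terms': 21},
 'ccc': {'R:dorsal': 0, 'R:ventral': 0, 'Int:dorsal': 5, 'Int:ventral': 0,
         'S:dorsal': 0, 'S:ventral': 0}}
```

Reading this: 70 simulated mice (58 defeated, 12 control) were
stratified by the GMM; 6400 cells across 4 cell types × 2 regions × 4
groups passed QC; 24 cell-type-level DE comparisons yielded 89
filtered DEGs, concentrated in the intermediate group's dorsal
stratum, where the generator planted them; and the inferred
communication network is non-empty **only** in Int-dorsal, where it
recovers exactly the five planted edges
(`results/demo/ccc_edges.tsv`):

```
group  region  source_type      ligand    target_type      receptor
Int    dorsal  endothelial      Ccl4      microglia        Ccr5
Int    dorsal  microglia        Serpine1  oligodendrocyte  Lrp1b
Int    dorsal  mural            Ccl5      microglia        Ccr5
Int    dorsal  oligodendrocyte  Ccl3      microglia        Ccr5
Int    dorsal  oligodendrocyte  Fgf1      oligodendrocyte  Fgfr2
```

Each module is also a subcommand (`stress-ccc simulate|stratify|
preprocess|de|enrich|ccc --help`) for running stages on your own
files: behavioral CSVs, MTX triplets with a metadata CSV, GMT
collections and ligand–receptor TSVs.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete default synthetic pipeline from scratch with the
given seed (tables land in `results/acceptance_run/`) and writes the
results JSON.  The scientific acceptance checks themselves — oracle
equivalence for the ligand–receptor rule and the exact Wilcoxon test,
planted-edge recovery, DE type-I calibration, GMM parameter recovery,
and the closed-form primitives — live in `tests/test_acceptance.py`.
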