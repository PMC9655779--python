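# Methods

`stress-ccc` re-implements, as a tested pipeline, an analysis chain for
chronic social defeat stress (CSDS) experiments in mice: behavioral
stratification of defeated animals into resilient (R), intermediate
(Int) and susceptible (S) sub-phenotypes, single-cell RNA-seq quality
control and normalization, per-cell-type differential expression
against controls, gene-set over-representation, and inference of a
directed ligand–receptor communication network between brain cell
types.  Because no public dataset accompanies the design this package
models, every stage is exercised against synthetic data with planted
ground truth; this note records the models, the defaults and what a
green test does and does not establish.

## Behavioral model

The social interaction (SI) index is `t_target / t_empty`: exploration
time of a mesh enclosure holding a CD1 aggressor over exploration of
the same enclosure when empty.  The modified social interaction (MSI)
index for each stimulus strain (CD1 or unfamiliar 129/Sv) is the
testing-phase exploration over the mean habituation-phase exploration
of the two empty enclosures.  Both indices are undefined when their
denominator is zero; the affected mouse raises an explicit error
rather than being dropped silently.

Defeated mice with extreme SI (< 0.75 or > 1.15, strict) are carried
forward.  Stratification is by a univariate three-component Gaussian
mixture on the SI index, fit by EM:

* **Initialization** — component means at the (i+0.5)/k quantiles, plus
  `n_starts − 1` seeded jitters (sd = 0.25 × sample sd); best
  log-likelihood wins.  Multiple starts guard against label collapse
  at the small n typical of behavioral cohorts (tens of mice).
* **Variance floor** — component variances are clamped at 1e-6 × total
  variance.  The clamp is the constrained M-step maximizer, so the
  log-likelihood trace remains monotone non-decreasing (property
  tested on arbitrary inputs).
* **Convergence** — log-likelihood change < 1e-8 or 500 iterations.
* **Variance structure** — by default the fitter runs EM under both
  the shared-variance and the free per-component-variance structures
  and keeps the lower-BIC model, the same selection the widely used
  packaged mixture fitter performs between its univariate E and V
  structures.  Fixing the most flexible (unequal) structure is
  tempting but measurably worse here: at a few dozen mice the
  unequal-variance MLE can broaden one component to absorb part of its
  neighbor, drifting the recovered means — we verified the drifted
  solutions are true likelihood optima (equal or better log-likelihood
  than an independent fitter), so the cure is model selection, not
  more restarts.  Both fixed structures remain available via
  ``var_structure``.
* **Labeling** — components sorted by ascending mean map to S < Int < R.
  Responsibility ties break toward the lower-mean component and carry
  an explicit flag.
* The mixture is fit on the SI index alone; `fit_gmm` accepts any
  numeric vector, so multivariate scores can be substituted by the
  caller, but univariate is the default and the tested path.

Threshold re-binning (R: SI > 1.15, S: SI < 0.50, Int: 0.50–0.75,
otherwise unclassified) is provided for treatment-shift comparisons;
phenotype proportions across experiments are compared with Pearson's
chi-squared test without continuity correction.  Variance
heterogeneity between groups uses the two-sided variance-ratio F test
with p = 2·min(upper, lower); sidedness is a package choice since
either convention fits a "variance ratio, p" report.  PCA of behavioral
variables is the eigendecomposition of the correlation matrix;
loadings are eigenvectors scaled by √eigenvalue, i.e. exactly the
correlations between standardized variables and component scores, with
each component's sign fixed so its largest-magnitude loading is
positive (reproducible across linear-algebra backends).

## Single-cell processing

Input is a CellRanger-style MTX triplet (genes × cells, 1-based
MatrixMarket coordinates) with a per-cell metadata CSV carrying mouse,
group (control/R/Int/S), region (dorsal/ventral), hemisphere and
cell-type/cluster label.  Graph-based clustering, UMAP and related
embedding steps are out of scope: cluster labels are inputs.

* **QC** — keep cells with mitochondrial count fraction < 0.15
  (strict) and detected features in [200, 2500] (inclusive at both
  ends; the bounds are configurable).  Mitochondrial genes are
  identified by prefix (default `mt-`); the fraction is computed on
  raw counts before any filtering.  Filtering is idempotent.
* **Normalization** — `ln(1 + count / cell_total × 10 000)`.  Per-cell
  totals are retained so the transform is exactly invertible (the
  round-trip is an acceptance check).
* **HVG selection** — genes ranked by binned standardized dispersion:
  variance of the log-normalized values, z-scored within 20 quantile
  bins of mean expression; top 2000 kept, ties broken by gene symbol
  so the ranking is invariant to input order.  This approximates the
  common dispersion-based selector without reproducing its exact
  constants.
* **Hemisphere pooling** — per (mouse, region) concatenation after
  aligning gene universes by symbol; hemisphere is retained in the
  metadata.
* **Annotation** — each cluster's top-10 one-vs-rest markers
  (rank-sum upregulation, smallest p first) are scored against
  user-supplied signatures with a hypergeometric tail over the full
  gene universe; best term wins, within-10× runner-ups are flagged
  ambiguous, zero overlap yields "unknown".  This in-repo signature
  scoring stands in for external annotation services.

## Differential expression

Two-sided Wilcoxon rank-sum per gene between a test and a reference
cell set, with cells as the unit of replication.  Genes must be
expressed (nonzero) in ≥ 10% of either set.  The reported fold change
is `ln(mean(expm1 x) + 1) − ln(mean(expm1 y) + 1)` — a natural-log fold
change of pseudocounted mean normalized expression.  The DEG filter is
|logFC| > 0.25 and Benjamini–Hochberg adjusted p < 0.05, both strict.
Panel summaries convert to log2 for display; ΔPCT is the difference in
expressing-cell fractions.  A "mimic bulk" mode pools all cell types
of a (group, region) stratum against the control stratum.

Numerical choices: groups with both sides ≤ 25 cells and no ties in a
gene's pooled values use the exact permutation distribution of the
rank-sum statistic; all other cases use the normal approximation with
tie and continuity corrections (with ties the "exact" enumeration
distribution is itself only approximate, so the corrected normal is
preferred).  Genes whose values are identical across both groups get
p = 1.  The natural-log scale of the 0.25 cut-off follows the
convention of the toolkit generation that popularized it; a config
switch is not needed because the threshold is a plain argument.

A mouse-aware pseudobulk mode is deliberately absent: the modeled
design tests cells, and the generator's mouse random effect exists
precisely so users can probe pseudo-replication sensitivity by raising
it.

## Enrichment

Hypergeometric upper tail `P(X ≥ k)` per term, BH across terms.  The
universe defaults to the genes tested for DE in the corresponding
stratum — not the genome — which is the defensible choice when the
query derives from that test set.  Collections are flat GMT sets; no
GO-hierarchy propagation is performed.  Only over-representation is
tested.

## Ligand–receptor network inference

The core rule: an edge `x --(L, R)--> y` is called when ligand L is in
the upregulated DEG set of cell type x, receptor R is in the
upregulated set of cell type y, and (L, R) occurs in the curated
reference (CellTalkDB dialect TSV).  "Upregulated" means avg_logfc > 0
after the DEG filter.  Genes upregulated in *any* sub-cluster of a
cell type count for that type (union rule).  Autocrine (x = y) edges
are allowed.  Matching is exact and case-sensitive after whitespace
stripping.  The method is presence/absence — no magnitude weighting
and no per-edge permutation test — and an empty network is a valid
result, not an error.  Summaries report per-(source, target) edge
counts (circos-ready adjacency), unique (ligand, receptor) pairs, and
per-gene in/out degrees; graph export uses networkx.

## Synthetic world

The generators encode one stated world; their defaults are never tuned
against test outcomes.

**Behavior** — 58 defeated and 12 control mice.  Defeated SI indices
follow an equal-weight mixture at means 0.40 / 0.65 / 1.30, sd 0.05
each; controls are N(1.2, 0.15).  MSI profiles per phenotype (CD1,
129/Sv): control (1.47, 1.54), R (1.15, 0.77), Int (0.71, 1.34),
S (0.53, 0.80) — the intermediate group interacts selectively with the
unfamiliar strain — with N(0, 0.1) noise.  Zone times are drawn so the
derived indices equal the sampled ones exactly (empty-enclosure times
uniform in plausible ranges).

**Counts** — negative binomial, mean/dispersion parameterization
(variance = μ + μ²/k, k = 2).  Four cell types (microglia,
oligodendrocytes, endothelial, mural), each with three elevated
(8-fold) marker genes; 13 `mt-` genes at a fixed baseline giving ~5%
mitochondrial fraction; remaining baselines lognormal with median 0.8
and σ = 1, which at the default 1000 genes yields ~500 detected
features and ~1300 total counts per cell — the scale of a typical
droplet experiment on dissociated brain tissue.  Planted fold changes
multiply the NB mean in a single (group, region, cell type) stratum,
so the true log fold change is ln(fc) exactly; planted genes get
baseline ≥ 1 so the effect is testable at a few hundred cells.  By
default only (Int, dorsal) strata carry effects: 15 generic DEGs per
cell type at fold change 3 plus the ligand/receptor genes of five
planted communication edges (within-oligodendrocyte Fgf1→Fgfr2,
microglial Serpine1→oligodendrocyte Lrp1b, and chemokines Ccl3/4/5
from three cell types onto microglial Ccr5).  Each group's cells split
over 3 mice carrying a lognormal random effect (sd 0.05 on the log
scale; set 0 for a clean null) and over both hemispheres.  The
ligand–receptor reference contains the planted pairs plus background
pairs drawn from non-planted genes of the same universe, so false
edges are possible in principle and their absence is informative.

What the generator does **not** emulate: ambient RNA, doublets,
dropout beyond NB sampling, UMI saturation, batch effects, cluster
structure within cell types, or damaged/low-quality cells — the
default world passes QC nearly untouched, so QC behavior is tested on
a dedicated fixture with planted violations rather than on the
simulation.  A green end-to-end test therefore establishes that the
pipeline recovers clean planted signal with calibrated error rates; it
says nothing about robustness to artifacts the generator omits.

## Degenerate inputs and tie-breaks (summary)

Zero denominators in indices, zero-total cells, zero-variance PCA
columns, empty cell sets, empty queries after universe intersection,
k > n mixtures and all-identical mixture inputs raise typed errors
naming the offender.  Ties: GMM responsibilities → lower-mean
component (flagged); HVG ranking → gene symbol; enrichment top-k →
larger overlap, then term id; edge lists sort by (source, target,
ligand, receptor).

## Limitations

Small-n behavioral mixtures can be genuinely ambiguous; the ARI ≥ 0.9
recovery level holds for the stated well-separated world, not for
arbitrary overlap.  The rank-sum test treats cells as independent;
with strong mouse effects this is anti-conservative, which is the
reason the generator exposes the mouse random effect.  The LR network
is a presence/absence construct over DEG calls — edge confidence
inherits all DE thresholds and the curation quality of the reference
list.
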