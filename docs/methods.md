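# Methods

This note documents the models and procedures `sigbridge` implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions a maintainer should know about.

## Gene-set library construction

Term tables (GMT or term/gene TSV) are merged with duplicate term ids
collapsed; the gene universe defaults to the union of all term genes.
Over-representation of a query gene list uses the one-sided hypergeometric
upper tail P(X ≥ k) — the de facto over-representation statistic — with
Benjamini–Hochberg adjustment across terms. Redundancy elimination is a
greedy pass in order of enrichment p (or term size when no enrichment was
run; ties broken by term id): a term is dropped when its Cohen's kappa to an
already-retained term exceeds the cutoff (default 0.5). Kappa is computed on
the 2×2 membership table over the universe, so it depends on the declared
universe; disjoint terms score ≤ 0 and identical terms score 1. The final
size filter keeps terms with at least 10 genes (inclusive). Gene identifiers
are treated as case-sensitive symbols; alias resolution is out of scope.

## Bulk clustering arm

**Preprocessing.** Expression (FPKM-like, non-negative) is restricted to the
signature gene set, log₂(x+1)-transformed, and z-scaled per gene (population
sd; zero-variance genes become zero columns rather than NaN), clipped to
±10. The unscaled log₂ layer is kept for marker statistics.

**MNN batch correction.** Batches merge in order of descending size. Mutual
k-nearest-neighbor pairs (k = 20) between the accumulated reference and the
incoming batch define pair difference vectors; each incoming sample is
corrected by a Gaussian-kernel-weighted average of those vectors. The kernel
bandwidth is 1.0 × the median incoming-to-anchor distance: a broad kernel
makes locally opposing pair differences cancel, so two identical batches
receive a near-zero correction while a constant shift survives the
averaging. Because MNN pairing preferentially selects pairs whose noise
opposes the shift, a single pass underestimates it (we measure ~75%
removal); the pairing/subtraction step therefore runs twice per merge
(`n_iter = 2`), which removes ≥ 95% of an additive shift in simulation.
Both the bandwidth fraction and the iteration count are parameters.

**Clustering.** PCA by full SVD (20 PCs for bulk, 15 for single-cell — both
config keys), then a shared-nearest-neighbor graph: any pair of samples is
connected with weight J = s/(2k − s), where s is the number of shared
members in their k-NN lists (self included), and edges with J < 1/15 are
pruned. Louvain modularity optimization (python-igraph) at resolution 0.5
with a seeded RNG gives deterministic labels; samples are processed in
sorted-id order so the result is invariant to input row order. Clusters
smaller than 3 samples — isolated fragments of the pruned graph — are folded
into the nearest cluster by PC-space centroid, and labels are re-indexed by
descending size (C1, C2, …).

**Conserved markers.** Per cluster and per sample-group level (default the
batch/project field): one-vs-rest Wilcoxon rank-sum per gene with BH
adjustment within each test; a marker is conserved when |log₂FC| ≥ 0.25 with
a consistent sign and adjusted p < 0.001 in *every* retained group (groups
with < 3 samples on either side are skipped with a warning); the combined p
is the maximum over groups. log₂FC is computed on group means of the linear
scale with pseudocount 1, i.e. log₂((mean_in+1)/(mean_out+1)). The cluster
signature is the top 20 up-markers by average log₂FC. The grouping variable
for "conserved" is a parameter because no single convention dominates;
project/batch is the default as the only grouping always available.

**Module scores.** Tirosh-style: mean expression of the gene set minus the
mean of control genes drawn from the same average-expression bins (24 bins,
100 controls per gene). Note the score measures deviation *relative to genes
of matched average expression*: a shift applied to the gene set in every
sample is absorbed into the bin averages and scores near zero by
construction; a shift present in a subset of samples is recovered at close
to its planted magnitude. Phase assignment takes the larger of the S and
G2M scores, "G1" when both are ≤ 0.

## Preranked enrichment

The ranking statistic is sorted descending with exact ties broken by a
seeded shuffle recorded in the output. The running sum increments by
|r|ʷ/N_R at set members (N_R the sum over members; weight w defaults to 1,
with w = 0 reducing exactly to the classic two-sample KS deviation) and
decrements by 1/(N − k) elsewhere; ES is the value at the maximal absolute
deviation. The leading edge is the members at or before the peak for
positive ES (at or after for negative).

The null is the ES of size-matched gene sets drawn uniformly without
replacement (gene-permutation null, vectorized and cached per set size).
The nominal p compares |ES| against the magnitudes of **all** null draws
with the +1 correction, p = (1 + #{|null| ≥ |ES|})/(1 + n_perm): this makes
p uniform under the null, bounded below by 1/(n_perm + 1), and attainably
small at n_perm = 1000 for the p < 0.001 similarity gate. (A same-sign-only
denominator would floor p near 2/n_perm and make that gate unreachable.)
NES divides ES by the mean |null ES| of the same sign — the standard
two-sided convention — and results with fewer than 10 same-sign null draws
are flagged unstable. FDR across terms is BH on nominal p, which matches the
"adjusted p" language used throughout the pipeline rather than the original
GSEA NES-binned FDR. Phenotype-permutation and single-sample GSEA are
non-goals.

## The cluster-similarity scan

Within one cell subset, genes are ranked by
log₂((mean_case + 1)/(mean_control + 1)) of counts-per-10k normalized
expression on the linear scale — a pseudobulk mean, not a per-cell test,
because the method consumes a single ranking vector. Every reference cluster
signature with ≥ 5 genes in the ranking is tested by preranked GSEA (one
seed stream per subset); a (subset, cluster) pair is **similar** when
NES > 0.1 and p < 0.001. These defaults follow the method's stated
thresholds; both are parameters since stricter variants (NES > 0.4, or
NES > 0.5 with adjusted p < 0.01) appear in practice. The enrichment core
of a called pair is carried to a per-gene Wilcoxon rank-sum between
conditions; "overexpressed" requires adjusted p < 0.001 and a positive
log-fold-change in the case arm. The same operations serve tissue-level
scans with samples in place of cells.

## Single-cell preparation

QC keeps cells with detected genes **strictly greater than** 1000 and
mitochondrial fraction **strictly below** 10% (both bounds exclusive, the
conservative reading of an ambiguous "at exactly the threshold" case).
The mitochondrial fraction comes from `obs["mito_frac"]` when precomputed,
otherwise from the "MT-" symbol prefix (overridable by an explicit list).
Normalization is log1p counts-per-10k — a deliberate substitution of a
monotone normalized layer for variance-stabilizing regression models, since
downstream operations here need only a monotone layer; raw counts are kept.
Subset annotation scores cluster mean profiles (not single cells) against a
marker database: genes are z-scored across clusters and each subset scores
Σ z·w over its positive markers minus the same over negatives, with
specificity weight w = 1/(number of subsets listing the marker). A call is
flagged low-confidence when the top score is below 0.25·√(markers scored).
Doublet detection and ambient-RNA correction are non-goals.

## Tissue differential expression

Size factors are DESeq-style median-of-ratios over genes expressed in every
sample, falling back to upper-quartile factors (scaled to geometric mean 1)
when no such gene exists. Note the formula is invariant to a *global*
rescaling of all counts (the per-gene geometric means rescale too); only
relative depth differences are absorbed. The NB Wald test is deliberately a
simplified closed form rather than a per-gene GLM: group means of
normalized counts estimate the NB means; per-gene NB2 dispersion comes from
pooled within-group moments, shrunk 50% in log space toward a fitted
a/μ + b trend (floor 1e-8); the delta-method standard error of the log₂
ratio uses Var(q̄) = n⁻² Σ (μ/s_j + α μ²); and p comes from the normal
reference. Measured on 2000 simulated null genes at n = 10/group this holds
the 5% level within ±2%, and planted log₂FC = 2 at dispersion 0.1 is
recovered within ±0.05 on average. One-sided zero group means get a
0.125-count guard; all-zero genes report p = 1, log₂FC = 0. DEG calling is
adjusted p < 0.05 and |log₂FC| ≥ 1 (the log₂ reading of "fold change greater
than 1", exposed as a flag). The VST layer is log₂(count/size factor + 1).
Age groups: young < 30, middle 30–50 inclusive, old > 50 years.
Gene–gene correlation uses Spearman (or Pearson) with a "correlated" flag at
|ρ| > 0.3 and the stated significance gate.

## Survival

Kaplan–Meier estimation and the k-group log-rank test delegate to lifelines;
the module fixes the conventions: censoring at an event time is processed
after the events, the median is the smallest t with S(t) ≤ 0.5 (NaN and
flagged when the curve never falls that far), and the k-group statistic is
referred to chi-square with k − 1 df. With no censoring the curve equals
1 − ECDF exactly. Pairwise tests with BH adjustment are provided as an
option; Cox regression is a non-goal.

## Synthetic data

The generators produce the statistical structure each stage assumes, not a
facsimile of any real accession.

* **Bulk cohort** (default 500 samples, 2000 genes): log-normal on the log₂
  scale (the bulk pipeline consumes log₂-transformed values), per-gene
  baselines Uniform(2, 8) — Uniform(4, 8) inside the 626-gene signature
  space so the +1 pseudocount barely biases planted shifts. Five clusters
  each carry a disjoint 20-gene signature block shifted by +1.0 log₂ (the
  block size equals the top-20 signature length so full recovery is
  well-defined). Two batches assigned round-robin differ by +0.8 log₂ on a
  random 30% of genes — detectable but removable by MNN. Survival is
  exponential per cluster with median PFS (10, 12, 13, 16, 14) months —
  the 16-vs-10 contrast between the best and worst planted clusters —
  under administrative censoring at 60 months plus exponential dropout
  (median 120 months), giving roughly 15–20% censoring.
* **Single-cell counts** (default 4 subsets × 2 conditions × 150 cells,
  2000 genes): NB2 counts with dispersion 0.5 over a log-normal relative
  expression profile; each subset has a 30-gene marker block up 2.0 log₂;
  the planted bridge signal up-shifts a supplied signature by 0.8 log₂ in
  the naive subset of the case condition only. Cell depth is log-normal
  around 6000 counts; a configurable fraction of cells gets a ~12× depth
  cut so their detected-gene count falls well below the 1000-gene QC bound,
  and the mitochondrial fraction is drawn per cell (stored as metadata)
  rather than simulated through MT- genes. Gene length/GC effects, dropout
  profiles, and doublets are deliberately not modeled, so passing tests
  demonstrate the statistical machinery, not robustness to those artifacts.
* **Tissue counts** (default 10 samples per age group, 2000 genes): NB2
  with dispersion 0.1, log-normal baselines around 100 counts, log-normal
  size factors, and 50 genes planted at +2 log₂ in the old-aged group.

All generators are deterministic given the config seed (independent seeded
streams per generator), and zero effect sizes produce exchangeable groups.

## Determinism and serialization

Every stochastic operation takes a seed; the pipeline derives per-stage
seeds from the global seed via SHA-256 (< 2³¹). Louvain runs under a seeded
RNG; tie-breaks (ranking ties, greedy redundancy order, cluster relabeling)
are all deterministic. Writers emit sorted keys and 6-significant-digit
floats so reruns are byte-identical.

## Known limitations

* The conserved-marker grouping variable, the GSEA weight (0 vs 1), and the
  similarity thresholds are genuinely underdetermined conventions; all are
  parameters with the defaults documented above.
* The simplified NB Wald test has no empirical-Bayes dispersion shrinkage;
  at very small n or extreme dispersions a full GLM framework will be better
  calibrated.
* MNN correction assumes batch effects are additive and shared across the
  batch; composition-specific (cluster × batch) effects are not modeled.
* Annotation operates on cluster profiles; per-cell annotation and
  confidence are out of scope.
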