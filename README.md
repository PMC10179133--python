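# sigbridge

Signature-restricted clustering of bulk lymphoma transcriptomes and
preranked-enrichment "bridging" against autoimmune B-cell data.

## The problem

Primary Sjögren syndrome (pSS) is a B-cell-mediated autoimmune disease that
in a minority of patients progresses to non-Hodgkin lymphoma, most severely
diffuse large B-cell lymphoma (DLBCL). A natural question is whether the
signaling programs that stratify DLBCL tumors are already detectable in the
B cells of pSS patients. `sigbridge` implements the full analysis chain for
that question, for computational biologists working with bulk cohorts,
single-cell count matrices, and tissue RNA-seq:

1. **Gene-set library construction** — merge user-supplied pathway/ontology
   term tables, test over-representation (one-sided hypergeometric,
   Benjamini–Hochberg FDR), eliminate redundant terms by Cohen's kappa on
   membership vectors (cutoff 0.5), and keep terms with ≥ 10 genes.
2. **Signature-restricted patient clustering** — log₂(x+1) transform and
   per-gene scaling restricted to the signaling gene set, sequential
   mutual-nearest-neighbor (MNN) batch correction, PCA (20 PCs), a shared
   nearest-neighbor graph with Jaccard weights, and Louvain clustering at
   resolution 0.5; per-cluster **conserved markers** (one-vs-rest Wilcoxon,
   |log₂FC| ≥ 0.25, adjusted p < 0.001 in every sample group) yield top-20
   **cluster signatures**.
3. **Preranked GSEA** — the weighted Kolmogorov–Smirnov running sum

   ES = max deviation of  Σ_{hits ≤ i} |r|ʷ / N_R − Σ_{misses ≤ i} 1/(N−k),

   with a size-matched gene-permutation null, NES = ES / mean |null ES| of
   the same sign, magnitude-based permutation p, and the leading edge
   ("enrichment core") at the running-sum peak.
4. **Cluster-similarity scan** — rank genes by the condition log-fold-change
   of mean normalized expression within one B-cell subset, test every tumor
   cluster signature by preranked GSEA, and call similarity at **NES > 0.1
   and p < 0.001**; the core genes of a called pair are then tested one by
   one between conditions.
5. **Support stages** — single-cell QC (> 1000 detected genes, < 10%
   mitochondrial), log1p counts-per-10k normalization, marker-score subset
   annotation; simplified negative-binomial Wald differential expression with
   median-of-ratios size factors (DEG: adjusted p < 0.05, |log₂FC| ≥ 1);
   Kaplan–Meier curves, median survival, and k-group log-rank tests.

A synthetic-data module generates bulk, single-cell, and tissue datasets with
planted ground truth (clusters, signatures, survival hazards, DEGs, QC
failure modes) so the whole chain is testable end to end.

## Worked example

```bash
python examples/02_cluster_bulk_cohort.py
```

```
found 5 clusters (ARI vs planted truth: 1.000)
  C1: top-20 signature, first 5 genes: ['G00019', 'G00008', 'G00018', 'G00004', 'G00009']
  ...
  C1: n=100, events=87, median PFS=10.4 months
  C2: n=100, events=76, median PFS=18.3 months
  ...
log-rank across clusters: chi2=16.58, df=4, p=0.0023
```

The adjusted Rand index of 1.0 says the signature-restricted clustering
recovered the five planted patient groups exactly; the per-cluster medians
track the planted exponential hazards, and the log-rank p-value shows the
clusters differ in progression-free survival. `examples/04_bridge_similarity_scan.py`
continues the chain: planting cluster C4's signature into the naive B-cell
subset of a simulated pSS cohort produces exactly one similarity call,

```
Naive  C4  ES=0.99  NES=2.93  p=0.000999  similar=True
(Naive, C4) called similar; 12/20 core genes overexpressed in pSS
```

i.e. the tumor-derived signature is detected in the autoimmune arm precisely
where it was planted, and its enrichment core decomposes into the genes that
are individually overexpressed.

The other examples cover library construction (`01`), preranked GSEA (`03`),
and tissue differential expression (`05`). A thin CLI wraps the same
functions (`sigbridge geneset | cluster | gsea | sc-prep | bridge | de |
survival | simulate | run`); `sigbridge run --seed 1 --outdir out/` executes
the synthetic end-to-end pipeline and writes all intermediate tables plus a
manifest.

Real data drop into the same entry points: bulk cohorts as genes × samples
TSV with a metadata TSV (GDC/TCGA-style FPKM), single-cell counts as a 10x
MatrixMarket triplet directory, gene sets as GMT, rankings as RNK.

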