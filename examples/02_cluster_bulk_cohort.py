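"""Cluster a bulk cohort on a signaling gene set and compare survival.

Simulates a 500-patient expression cohort with five planted signature-defined
clusters and cluster-dependent progression-free survival, then runs the bulk
arm: signature-restricted preprocessing, mutual-nearest-neighbor batch
correction, SNN/Louvain clustering, conserved-marker signatures, and
Kaplan-Meier / log-rank comparison of the recovered clusters.
"""

from sklearn.metrics import adjusted_rand_score

from sigbridge.cluster import conserved_markers, mnn_correct, preprocess_bulk, reduce_and_cluster
from sigbridge.simulate import SimConfig, simulate_bulk_cohort
from sigbridge.surv import km_by_group, logrank_test

cohort = simulate_bulk_cohort(SimConfig(seed=1))
pre = preprocess_bulk(cohort.expr, cohort.signature_space)
corrected = mnn_correct(pre, "batch")
corrected.layers = pre.layers

assign, _ = reduce_and_cluster(corrected, n_pcs=20, k_nn=20, resolution=0.5, seed=1)
print(f"found {assign.n_clusters} clusters "
      f"(ARI vs planted truth: {adjusted_rand_score(cohort.labels, assign.labels):.3f})")

markers, signatures = conserved_markers(corrected, assign, group_key="batch")
for cl, sig in sorted(signatures.items()):
    print(f"  {cl}: top-20 signature, first 5 genes: {sig[:5]}")

surv = cohort.survival.assign(group=assign.labels.loc[cohort.survival["sample"]].to_numpy())
for g, curve in sorted(km_by_group(surv).items()):
    print(f"  {g}: n={curve.n}, events={curve.n_events}, median PFS={curve.median:.1f} months")
res = logrank_test(surv)
print(f"log-rank across clusters: chi2={res['statistic']:.2f}, df={res['df']}, p={res['p']:.2g}")
# A high ARI means the signature-restricted clustering recovers the planted
# patient groups; the per-cluster medians track the planted hazards, and the
# log-rank p-value quantifies how distinct the survival profiles are.
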