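"""Bulk clustering: preprocessing, MNN correction, SNN/Louvain, markers, scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sigbridge.containers import ExpressionMatrix
from sigbridge.cluster import (
    conserved_markers,
    mnn_correct,
    module_score,
    phase_assign,
    preprocess_bulk,
    reduce_and_cluster,
)


def make_em(X, meta=None, genes=None):
    idx = [f"s{i:03d}" for i in range(X.shape[0])]
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    meta = pd.DataFrame(meta, index=idx) if meta is not None else None
    return ExpressionMatrix(pd.DataFrame(X, index=idx, columns=genes), meta)


class TestPreprocess:
    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        em = make_em(rng.lognormal(2, 1, size=(50, 10)))
        pre = preprocess_bulk(em, [f"g{j}" for j in range(10)])
        X = pre.values.to_numpy()
        assert np.allclose(X.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(X.std(axis=0, ddof=0), 1, atol=1e-9)

    def test_zero_variance_gene_scales_to_zeros(self):
        X = np.ones((20, 3))
        X[:, 1] = np.arange(20)
        pre = preprocess_bulk(make_em(X), ["g0", "g1", "g2"])
        assert (pre.values["g0"] == 0).all()
        assert not pre.values["g1"].isna().any()

    def test_zero_maps_to_zero_via_pseudocount(self):
        X = np.zeros((5, 2))
        X[0, 0] = 3.0
        pre = preprocess_bulk(make_em(X), ["g0", "g1"])
        assert pre.layers["log2"].iloc[1, 0] == 0.0  # log2(0+1) = 0

    def test_too_few_signature_genes_rejected(self):
        em = make_em(np.random.rand(10, 5))
        with pytest.raises(ValueError, match="signature genes"):
            preprocess_bulk(em, ["g0", "absent1", "absent2"])


class TestMnnCorrect:
    def test_identical_batches_barely_corrected(self):
        """Two copies of the same samples in different batches: nothing to correct."""
        rng = np.random.default_rng(1)
        half = rng.normal(size=(60, 15))
        X = np.vstack([half, half])
        em = make_em(X, {"batch": ["B1"] * 60 + ["B2"] * 60})
        out = mnn_correct(em, "batch", k=10)
        assert np.abs(out.values.to_numpy() - X).mean() < 0.05

    def test_additive_shift_removed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 20))
        batch = np.array(["B1", "B2"] * 100)
        shift = np.zeros(20)
        shift[:8] = 2.0
        X[batch == "B2"] += shift
        em = make_em(X, {"batch": batch})
        before = np.linalg.norm(
            X[batch == "B1"].mean(axis=0) - X[batch == "B2"].mean(axis=0)
        )
        out = mnn_correct(em, "batch", k=20)
        Y = out.values.to_numpy()
        after = np.linalg.norm(Y[batch == "B1"].mean(axis=0) - Y[batch == "B2"].mean(axis=0))
        assert after <= 0.2 * before

    def test_single_batch_identity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        em = make_em(X, {"batch": ["B1"] * 30})
        out = mnn_correct(em, "batch")
        np.testing.assert_array_equal(out.values.to_numpy(), X)


class TestReduceAndCluster:
    def test_separated_blobs_perfectly_recovered(self, blobs):
        assign, _ = reduce_and_cluster(blobs, n_pcs=5, k_nn=10, seed=0)
        assert assign.n_clusters == 2
        assert adjusted_rand_score(blobs.meta["truth"], assign.labels) == 1.0

    def test_deterministic_under_seed(self, blobs):
        a, _ = reduce_and_cluster(blobs, n_pcs=5, k_nn=10, seed=4)
        b, _ = reduce_and_cluster(blobs, n_pcs=5, k_nn=10, seed=4)
        assert (a.labels == b.labels).all()

    def test_invariant_to_sample_order(self, blobs):
        perm = np.random.default_rng(5).permutation(blobs.n_samples)
        shuffled = ExpressionMatrix(blobs.values.iloc[perm], blobs.meta.iloc[perm])
        a, _ = reduce_and_cluster(blobs, n_pcs=5, k_nn=10, seed=6)
        b, _ = reduce_and_cluster(shuffled, n_pcs=5, k_nn=10, seed=6)
        joined = pd.concat([a.labels.rename("a"), b.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_planted_cluster_recovery_on_reduced_cohort(self, small_cohort):
        cfg, cohort = small_cohort
        pre = preprocess_bulk(cohort.expr, cohort.signature_space)
        corrected = mnn_correct(pre, "batch")
        corrected.layers = pre.layers
        assign, _ = reduce_and_cluster(corrected, n_pcs=10, k_nn=15, seed=7)
        assert adjusted_rand_score(cohort.labels, assign.labels) >= 0.9

    def test_pca_variance_ordering_monotone(self, blobs):
        _, pcs = reduce_and_cluster(blobs, n_pcs=5, k_nn=10, seed=8)
        var = pcs.var(axis=0).to_numpy()
        assert (np.diff(var) <= 1e-9).all()

    def test_k_nn_too_large_rejected(self, blobs):
        with pytest.raises(ValueError):
            reduce_and_cluster(blobs, k_nn=200)


class TestConservedMarkers:
    @pytest.fixture()
    def clustered_cohort(self, small_cohort):
        cfg, cohort = small_cohort
        pre = preprocess_bulk(cohort.expr, cohort.signature_space)
        from sigbridge.cluster import ClusterAssignment

        assign = ClusterAssignment(cohort.labels, resolution=0.5, seed=0)
        return cohort, pre, assign

    def test_planted_markers_detected_and_capped_at_top20(self, clustered_cohort):
        cohort, pre, assign = clustered_cohort
        table, sigs = conserved_markers(pre, assign, group_key="batch")
        for cl, planted in cohort.signatures.items():
            assert len(sigs[cl]) <= 20
            overlap = len(set(sigs[cl]) & set(planted)) / len(planted)
            assert overlap >= 0.8

    def test_flat_gene_never_a_marker(self, clustered_cohort):
        cohort, pre, assign = clustered_cohort
        table, _ = conserved_markers(pre, assign, group_key="batch")
        planted = {g for genes in cohort.signatures.values() for g in genes}
        # markers overwhelmingly come from the planted blocks
        assert (~table["gene"].isin(planted)).mean() < 0.2

    def test_marker_sign_antisymmetry(self, clustered_cohort):
        """Swapping cluster-vs-rest flips the sign of the fold change."""
        cohort, pre, assign = clustered_cohort
        from sigbridge.cluster import _group_stats

        X = pre.layers["log2"].to_numpy()
        in_mask = (assign.labels == "C1").to_numpy()
        _, lfc_fwd, _, _ = _group_stats(X, in_mask, ~in_mask)
        _, lfc_rev, _, _ = _group_stats(X, ~in_mask, in_mask)
        np.testing.assert_allclose(lfc_fwd, -lfc_rev, atol=1e-9)

    def test_single_cluster_rejected(self, clustered_cohort):
        cohort, pre, assign = clustered_cohort
        from sigbridge.cluster import ClusterAssignment

        one = ClusterAssignment(pd.Series("C1", index=pre.values.index), 0.5, 0)
        with pytest.raises(ValueError):
            conserved_markers(pre, one)


class TestModuleScore:
    def test_random_set_centers_near_zero(self):
        rng = np.random.default_rng(9)
        em = make_em(rng.normal(size=(500, 300)))
        score = module_score(em, [f"g{j}" for j in range(0, 300, 15)], seed=0)
        assert abs(float(score.mean())) < 0.05

    def test_planted_shift_recovered(self):
        """A +0.7 shift of the gene set in 5% of samples scores ~0.7 in those samples."""
        rng = np.random.default_rng(10)
        n, g = 400, 1000
        base = rng.uniform(0, 5, size=g)
        X = base[None, :] + rng.normal(size=(n, g))
        target = [f"g{j}" for j in range(0, 1000, 100)]  # 10 genes across bins
        active = np.arange(20)  # 5% of samples
        X[np.ix_(active, range(0, 1000, 100))] += 0.7
        em = make_em(X)
        score = module_score(em, target, seed=1)
        assert float(score.iloc[active].mean()) == pytest.approx(0.7, abs=0.1)
        assert abs(float(score.iloc[len(active):].mean())) < 0.1

    def test_phase_argmax_rule(self):
        s = pd.Series([0.3, -0.1, -0.2], index=list("abc"))
        g2m = pd.Series([0.1, 0.2, -0.1], index=list("abc"))
        phases = phase_assign(s, g2m)
        assert list(phases) == ["S", "G2M", "G1"]
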