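"""Signature-restricted clustering of bulk transcriptomes.

The cohort is clustered at single-patient resolution restricted to a
signaling gene set: log2 transform and per-gene scaling, sequential
mutual-nearest-neighbor (MNN) batch correction, PCA, a shared-nearest-neighbor
(SNN) graph with Jaccard edge weights, and Louvain modularity clustering.
Cluster signatures are the top conserved markers — genes that pass the
fold-change and adjusted-p thresholds one-vs-rest consistently in every
sample group (by default the source project/batch).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from sigbridge.containers import ExpressionMatrix
from sigbridge.genesets import bh_adjust

logger = logging.getLogger(__name__)

#: SNN edges with Jaccard weight below this are pruned (Seurat-style default)
SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    """Sample -> cluster labels ("C1".."CK", ordered by descending size)."""

    labels: pd.Series
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()

    def members(self, cluster: str) -> pd.Index:
        return self.labels.index[self.labels == cluster]


def preprocess_bulk(matrix: ExpressionMatrix, signature_genes, clip: float = 10.0) -> ExpressionMatrix:
    """Restrict to signature genes, log2(x+1) transform, z-scale per gene.

    Zero-variance genes scale to all-zero columns; scaled values are clipped
    to ``[-clip, clip]``.  The unscaled log2 layer is kept as
    ``layers["log2"]`` for marker statistics.
    """
    present = [g for g in signature_genes if g in matrix.values.columns]
    missing_frac = 1.0 - len(present) / max(len(list(signature_genes)), 1)
    if len(present) < 2:
        raise ValueError(
            f"fewer than 2 signature genes found in the matrix ({missing_frac:.0%} missing)"
        )
    if missing_frac > 0:
        logger.warning("%.1f%% of signature genes absent from the matrix", 100 * missing_frac)
    vals = matrix.values[present].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative before log transform")
    log2 = np.log2(vals + 1.0)
    mean = log2.mean(axis=0)
    sd = log2.std(axis=0)
    scaled = np.zeros_like(log2)
    ok = sd > 0
    scaled[:, ok] = (log2[:, ok] - mean[ok]) / sd[ok]
    scaled = np.clip(scaled, -clip, clip)
    idx = matrix.values.index
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=idx, columns=present),
        matrix.meta.copy(),
        layers={"log2": pd.DataFrame(log2, index=idx, columns=present)},
    )


def _mnn_pairs(ref: np.ndarray, new: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    nn_ref = NearestNeighbors(n_neighbors=k).fit(ref)
    nn_new = NearestNeighbors(n_neighbors=k).fit(new)
    ref_of_new = nn_ref.kneighbors(new, return_distance=False)  # new -> ref
    new_of_ref = nn_new.kneighbors(ref, return_distance=False)  # ref -> new
    ref_nbr = {(i, j) for i in range(ref.shape[0]) for j in new_of_ref[i]}
    pairs = [(i, j) for j in range(new.shape[0]) for i in ref_of_new[j] if (i, j) in ref_nbr]
    if not pairs:
        return np.array([], int), np.array([], int)
    return np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])


def mnn_correct(
    matrix: ExpressionMatrix,
    batch_key: str,
    k: int = 20,
    sigma_frac: float = 1.0,
    n_iter: int = 2,
) -> ExpressionMatrix:
    """Sequential pairwise mutual-nearest-neighbor batch correction.

    Batches are merged in order of descending size.  For each incoming batch,
    mutual k-nearest-neighbor pairs against the accumulated reference define
    per-pair difference vectors; each incoming sample is corrected by a
    Gaussian-kernel-smoothed average of those vectors (kernel bandwidth =
    ``sigma_frac`` x the median incoming-to-anchor distance; the broad default
    lets locally opposing pair differences cancel, so truly identical batches
    receive a near-zero correction).  Because MNN pairing preferentially
    selects pairs whose noise opposes the batch shift, a single pass
    underestimates it; the pairing/subtraction step is repeated ``n_iter``
    times per merge, re-pairing on the partially corrected coordinates.
    A batch with no mutual pairs is left uncorrected with a warning.
    """
    batches = matrix.meta[batch_key]
    levels = batches.value_counts().index.tolist()  # descending size
    if len(levels) < 2:
        return matrix.copy()
    X = matrix.values.to_numpy(dtype=float).copy()
    order = {b: np.flatnonzero((batches == b).to_numpy()) for b in levels}
    ref_rows = order[levels[0]]
    for b in levels[1:]:
        new_rows = order[b]
        kk = min(k, len(ref_rows), len(new_rows))
        for _ in range(max(n_iter, 1)):
            pi, pj = _mnn_pairs(X[ref_rows], X[new_rows], kk)
            if pi.size == 0:
                logger.warning("batch %s has no mutual neighbors; left uncorrected", b)
                break
            diffs = X[ref_rows[pi]] - X[new_rows[pj]]
            anchors = X[new_rows[pj]]
            d2 = cdist(X[new_rows], anchors, "sqeuclidean")
            med = np.median(np.sqrt(d2))
            sigma = max(sigma_frac * med, 1e-12)
            w = np.exp(-d2 / (2.0 * sigma**2))
            wsum = w.sum(axis=1, keepdims=True)
            wsum[wsum == 0] = 1.0
            X[new_rows] += (w / wsum) @ diffs
        ref_rows = np.concatenate([ref_rows, new_rows])
    out = matrix.copy()
    out.values = pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns)
    return out


def _snn_graph(X: np.ndarray, k_nn: int, prune: float = SNN_PRUNE) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard weights over k-NN sets.

    Any pair of samples sharing neighbors is connected (not just k-NN pairs);
    edges with Jaccard weight below ``prune`` are dropped.
    """
    from scipy import sparse

    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=k_nn).fit(X)
    idx = nn.kneighbors(X, return_distance=False)  # row i includes i itself
    rows = np.repeat(np.arange(n), k_nn)
    A = sparse.csr_matrix((np.ones(n * k_nn), (rows, idx.ravel())), shape=(n, n))
    shared = (A @ A.T).tocoo()  # shared-neighbor counts
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * k_nn - s)
    keep = jac >= prune
    g = igraph.Graph(n=n, edges=list(zip(r[keep], c[keep])))
    g.es["weight"] = jac[keep]
    return g


def reduce_and_cluster(
    matrix: ExpressionMatrix,
    n_pcs: int = 20,
    k_nn: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
    min_cluster_size: int = 3,
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """PCA -> SNN graph -> Louvain clustering of samples.

    Clusters smaller than ``min_cluster_size`` (isolated fragments of the
    pruned SNN graph) are merged into the nearest cluster by PC-space
    centroid.  Returns the cluster assignment (labels "C1".. ordered by
    descending cluster size) and the PC score frame.  Deterministic given
    ``seed``.
    """
    n = matrix.n_samples
    if k_nn >= n:
        raise ValueError("k_nn must be smaller than the number of samples")
    if n <= n_pcs:
        raise ValueError("need more samples than principal components")
    # sort samples for order invariance, restore afterwards
    order = np.argsort(matrix.values.index.to_numpy())
    X = matrix.values.to_numpy(dtype=float)[order]
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    g = _snn_graph(scores, k_nn=k_nn)
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    membership = np.asarray(part.membership)
    # fold fragments (clusters below min_cluster_size, e.g. samples isolated by
    # SNN pruning) into the nearest substantive cluster by PC-space centroid
    sizes0 = pd.Series(membership).value_counts()
    big = sizes0.index[sizes0 >= min_cluster_size]
    if len(big) and len(big) < len(sizes0):
        centroids = np.vstack([scores[membership == b].mean(axis=0) for b in big])
        small_rows = np.flatnonzero(~np.isin(membership, big))
        nearest = np.argmin(cdist(scores[small_rows], centroids), axis=1)
        membership[small_rows] = np.asarray(big)[nearest]
    # relabel by descending cluster size (ties by original label for determinism)
    sizes = pd.Series(membership).value_counts()
    relabel = {old: f"C{rank + 1}" for rank, old in enumerate(sizes.index)}
    labels_sorted = pd.Series(
        [relabel[m] for m in membership], index=matrix.values.index[order], name="cluster"
    )
    labels = labels_sorted.loc[matrix.values.index]
    pcs = pd.DataFrame(
        scores,
        index=matrix.values.index[order],
        columns=[f"PC{i + 1}" for i in range(n_pcs)],
    ).loc[matrix.values.index]
    return ClusterAssignment(labels, resolution, seed), pcs


def _log2_layer(matrix: ExpressionMatrix) -> pd.DataFrame:
    return matrix.layers.get("log2", matrix.values)


def _group_stats(log2: np.ndarray, in_mask: np.ndarray, out_mask: np.ndarray):
    """Per-gene rank-sum p, log2FC of group means, and expression fractions."""
    a, b = log2[in_mask], log2[out_mask]
    with np.errstate(invalid="ignore"):
        res = mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    lin_a = np.expm1(a * np.log(2.0)).mean(axis=0)  # mean of 2^v - 1
    lin_b = np.expm1(b * np.log(2.0)).mean(axis=0)
    lfc = np.log2(lin_a + 1.0) - np.log2(lin_b + 1.0)
    pct_in = (a > 0).mean(axis=0)
    pct_out = (b > 0).mean(axis=0)
    return p, lfc, pct_in, pct_out


def conserved_markers(
    matrix: ExpressionMatrix,
    clusters: ClusterAssignment,
    group_key: str | None = None,
    fc_min: float = 0.25,
    p_max: float = 0.001,
    top_k: int = 20,
    min_group_n: int = 3,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-vs-rest conserved markers per cluster and top-``top_k`` signatures.

    Statistics run on the log2 layer: Wilcoxon rank-sum per gene per group
    level with Benjamini-Hochberg adjustment within each (cluster, group)
    test; a marker is conserved when |log2FC| >= ``fc_min`` with a consistent
    sign and adjusted p < ``p_max`` in every retained group; the combined p is
    the max over groups.  Signatures are the ``top_k`` up-markers ordered by
    average log2FC descending.
    """
    if clusters.n_clusters < 2:
        raise ValueError("conserved markers need at least 2 clusters")
    log2 = _log2_layer(matrix)
    genes = log2.columns
    X = log2.to_numpy(dtype=float)
    if group_key is None:
        groups = pd.Series("all", index=matrix.values.index)
    else:
        groups = matrix.meta[group_key].astype(str)
    levels = sorted(groups.unique())
    rows = []
    signatures: dict[str, list[str]] = {}
    for cl in sorted(clusters.labels.unique()):
        in_cluster = (clusters.labels == cl).to_numpy()
        per_group = []
        for lev in levels:
            gm = (groups == lev).to_numpy()
            in_mask = in_cluster & gm
            out_mask = ~in_cluster & gm
            if in_mask.sum() < min_group_n or out_mask.sum() < min_group_n:
                logger.warning("cluster %s: group %s skipped (too few samples)", cl, lev)
                continue
            p, lfc, pct_in, pct_out = _group_stats(X, in_mask, out_mask)
            per_group.append((p, bh_adjust(p), lfc, pct_in, pct_out))
        if not per_group:
            logger.warning("cluster %s has no usable groups", cl)
            signatures[cl] = []
            continue
        p_all = np.vstack([g[0] for g in per_group])
        adj_all = np.vstack([g[1] for g in per_group])
        lfc_all = np.vstack([g[2] for g in per_group])
        pct_in_m = np.vstack([g[3] for g in per_group]).mean(axis=0)
        pct_out_m = np.vstack([g[4] for g in per_group]).mean(axis=0)
        avg_lfc = lfc_all.mean(axis=0)
        sign_ok = (np.sign(lfc_all) == np.sign(avg_lfc)).all(axis=0) & (avg_lfc != 0)
        passes = (np.abs(lfc_all) >= fc_min).all(axis=0) & (adj_all < p_max).all(axis=0) & sign_ok
        comb_p = p_all.max(axis=0)
        comb_adj = adj_all.max(axis=0)
        for j in np.flatnonzero(passes):
            rows.append(
                (cl, genes[j], avg_lfc[j], comb_p[j], comb_adj[j], pct_in_m[j], pct_out_m[j])
            )
        up = [(avg_lfc[j], genes[j]) for j in np.flatnonzero(passes) if avg_lfc[j] > 0]
        up.sort(key=lambda t: (-t[0], t[1]))
        signatures[cl] = [g for _, g in up[:top_k]]
    table = pd.DataFrame(
        rows, columns=["cluster", "gene", "avg_log2FC", "p", "adj_p", "pct_expr_in", "pct_expr_out"]
    )
    return table, signatures


def module_score(
    matrix: ExpressionMatrix,
    geneset,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin-matched module score (Tirosh-style).

    Mean expression of the gene set minus the mean of control genes sampled
    from the same average-expression bins.  Scores center near zero for a
    random gene set on exchangeable data.
    """
    vals = matrix.values
    present = [g for g in geneset if g in vals.columns]
    if len(present) < 2:
        raise ValueError("fewer than 2 gene-set genes present in the matrix")
    rng = np.random.default_rng(seed)
    avg = vals.mean(axis=0)
    ranks = avg.rank(method="first")
    bins = np.ceil(ranks / (len(ranks) / n_bins)).astype(int)
    ctrl: list[str] = []
    for g in present:
        pool = bins.index[bins == bins[g]].tolist()
        take = min(n_ctrl, len(pool))
        if take < n_ctrl:
            logger.warning("control pool for bin of %s has only %d genes", g, take)
        ctrl.extend(rng.choice(pool, size=take, replace=False))
    score = vals[present].mean(axis=1) - vals[list(ctrl)].mean(axis=1)
    score.name = "module_score"
    return score


def phase_assign(score_s: pd.Series, score_g2m: pd.Series) -> pd.Series:
    """Cell-cycle phase call: larger of the two scores, 'G1' if both <= 0."""
    out = pd.Series("G1", index=score_s.index, name="phase")
    s_wins = (score_s > score_g2m) & (score_s > 0)
    g_wins = (score_g2m >= score_s) & (score_g2m > 0)
    out[s_wins] = "S"
    out[g_wins] = "G2M"
    return out
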