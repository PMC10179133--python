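"""Single-cell preparation: QC, normalization, clustering, subset annotation.

Cells pass QC when they have more than ``min_genes`` detected genes AND a
mitochondrial fraction strictly below ``max_mito`` (both bounds strict, so a
cell at exactly 1000 genes or exactly 10% mitochondrial reads is removed).
Counts are normalized to log1p counts-per-10k.  Subset annotation scores
cluster mean profiles against a marker database with specificity weights
(a marker listed by several subsets discriminates less).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from sigbridge.containers import ExpressionMatrix
from sigbridge.cluster import ClusterAssignment, reduce_and_cluster

logger = logging.getLogger(__name__)


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def mito_fraction(adata: ad.AnnData, mito_prefix: str = "MT-", mito_genes=None) -> np.ndarray:
    """Per-cell mitochondrial count fraction from gene names (or an explicit list)."""
    if mito_genes is not None:
        mask = adata.var_names.isin(list(mito_genes))
    else:
        mask = adata.var_names.str.startswith(mito_prefix)
    X = _dense(adata.X)
    total = X.sum(axis=1)
    total[total == 0] = 1.0
    return X[:, mask].sum(axis=1) / total


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 1000,
    max_mito: float = 0.10,
    mito_prefix: str = "MT-",
    mito_genes=None,
) -> tuple[ad.AnnData, dict[str, int]]:
    """Keep cells with detected genes > ``min_genes`` and mito fraction < ``max_mito``.

    The mitochondrial fraction is taken from ``obs["mito_frac"]`` when
    present, otherwise computed from gene names.  Returns the filtered copy
    and a report of removal counts per criterion.
    """
    X = _dense(adata.X)
    detected = (X > 0).sum(axis=1)
    if "mito_frac" in adata.obs:
        mito = adata.obs["mito_frac"].to_numpy(dtype=float)
    else:
        mito = mito_fraction(adata, mito_prefix=mito_prefix, mito_genes=mito_genes)
    keep = (detected > min_genes) & (mito < max_mito)
    report = {
        "n_input": int(adata.n_obs),
        "removed_low_genes": int((detected <= min_genes).sum()),
        "removed_high_mito": int((mito >= max_mito).sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        raise ValueError("QC filter removed every cell")
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = detected[keep]
    return out, report


def normalize_cells(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Store log1p counts-per-``scale`` in ``layers["lognorm"]``; raw counts kept."""
    X = _dense(adata.X)
    total = X.sum(axis=1)
    if (total == 0).any():
        raise ValueError("zero-total cell encountered (run qc_filter first)")
    out = adata.copy()
    out.layers["lognorm"] = np.log1p(X / total[:, None] * scale)
    return out


def cluster_cells(
    adata: ad.AnnData,
    n_pcs: int = 15,
    k_nn: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster cells on the normalized layer (PCA + SNN + Louvain, 15 PCs)."""
    if "lognorm" not in adata.layers:
        raise ValueError("normalize_cells must run before clustering")
    em = ExpressionMatrix(
        pd.DataFrame(np.asarray(adata.layers["lognorm"]), index=adata.obs_names, columns=adata.var_names)
    )
    assign, _ = reduce_and_cluster(em, n_pcs=n_pcs, k_nn=k_nn, resolution=resolution, seed=seed)
    return assign


@dataclass
class MarkerDB:
    """Subset label -> positive (and optional negative) marker genes."""

    positive: dict[str, list[str]]
    negative: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sub, pos in self.positive.items():
            neg = set(self.negative.get(sub, []))
            if neg & set(pos):
                raise ValueError(f"subset {sub}: positive and negative markers overlap")


def cluster_profiles(adata: ad.AnnData, clusters: ClusterAssignment) -> pd.DataFrame:
    """Mean normalized expression per cluster (clusters x genes)."""
    ln = pd.DataFrame(
        np.asarray(adata.layers["lognorm"]), index=adata.obs_names, columns=adata.var_names
    )
    return ln.groupby(clusters.labels).mean()


#: a top score below this multiple of sqrt(#markers scored) is low confidence
LOW_CONFIDENCE_FACTOR = 0.25


def annotate_subsets(profiles: pd.DataFrame, markers: MarkerDB) -> pd.DataFrame:
    """Label each cluster profile with the best-scoring subset.

    Genes are z-scored across clusters; score(subset) = sum over positive
    markers of z * w minus the same over negative markers, with specificity
    weight w = 1 / (number of subsets listing the marker).  Markers absent
    from the profiles are dropped with a warning.  The call is flagged low
    confidence when the top score is below 0.25 * sqrt(#markers scored).
    """
    mean = profiles.mean(axis=0)
    sd = profiles.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (profiles - mean) / sd
    listing: dict[str, int] = {}
    for sub in markers.positive:
        for g in set(markers.positive[sub]) | set(markers.negative.get(sub, [])):
            listing[g] = listing.get(g, 0) + 1
    rows = []
    for cl in profiles.index:
        scores = {}
        n_used = {}
        for sub, pos in markers.positive.items():
            pos_here = [g for g in pos if g in z.columns]
            if len(pos_here) < len(pos):
                logger.warning("subset %s: %d markers absent", sub, len(pos) - len(pos_here))
            if not pos_here:
                raise ValueError(f"subset {sub} has no positive markers in the matrix")
            s = sum(z.loc[cl, g] / listing[g] for g in pos_here)
            neg_here = [g for g in markers.negative.get(sub, []) if g in z.columns]
            s -= sum(z.loc[cl, g] / listing[g] for g in neg_here)
            scores[sub] = s
            n_used[sub] = len(pos_here) + len(neg_here)
        best = max(scores, key=lambda s: (scores[s], s))
        low = scores[best] < LOW_CONFIDENCE_FACTOR * np.sqrt(n_used[best])
        rows.append((cl, best, scores[best], low))
    return pd.DataFrame(rows, columns=["cluster", "subset", "score", "low_confidence"]).set_index(
        "cluster"
    )


def annotate_cells(
    adata: ad.AnnData, clusters: ClusterAssignment, markers: MarkerDB, key: str = "subset_pred"
) -> ad.AnnData:
    """Propagate cluster-level subset labels onto cells (stored in ``obs[key]``)."""
    ann = annotate_subsets(cluster_profiles(adata, clusters), markers)
    out = adata.copy()
    out.obs[key] = clusters.labels.map(ann["subset"]).to_numpy()
    out.obs[key + "_low_confidence"] = clusters.labels.map(ann["low_confidence"]).to_numpy()
    return out
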