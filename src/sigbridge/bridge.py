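"""Cluster-similarity scan between reference signatures and condition shifts.

Genes are ranked by the between-condition log2 fold change of mean normalized
expression within one cell subset (or tissue sample group); every reference
cluster signature is then tested against that ranking by preranked GSEA.
A (subset, cluster) pair is called similar when NES exceeds ``nes_min`` and
the nominal p falls below ``p_max``; the enrichment core (leading edge) of a
called signature is carried forward to a per-gene differential test between
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from sigbridge.genesets import bh_adjust
from sigbridge.gsea import RankedList, gsea_preranked, rank_genes

logger = logging.getLogger(__name__)


@dataclass
class SimilarityCall:
    """One (subset, reference cluster) similarity test."""

    subset: str
    cluster: str
    es: float
    nes: float
    p: float
    q: float
    similar: bool
    core_genes: list[str]
    flagged: bool = False  # insufficient overlap or unstable null
    overexpressed_core: pd.DataFrame | None = field(default=None, repr=False)


def _cp10k(X: np.ndarray, scale: float = 1e4) -> np.ndarray:
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return X / total * scale


def group_fold_change(
    cells: ad.AnnData,
    subset: str,
    cond_a: str,
    cond_b: str,
    subset_key: str = "subset",
    cond_key: str = "condition",
    pseudocount: float = 1.0,
    tie_seed: int = 0,
    min_cells: int = 10,
) -> RankedList:
    """Rank genes by log2((mean_a + pc) / (mean_b + pc)) within one subset.

    Means are per-group means of counts-per-10k normalized expression on the
    linear scale (pseudobulk means), giving a single ranking vector for GSEA.
    """
    obs = cells.obs
    in_subset = (obs[subset_key] == subset).to_numpy()
    mask_a = in_subset & (obs[cond_key] == cond_a).to_numpy()
    mask_b = in_subset & (obs[cond_key] == cond_b).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(f"subset {subset!r} absent in one of the conditions")
    if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
        raise ValueError(f"subset {subset!r} has fewer than {min_cells} cells in a condition")
    X = cells.X.toarray() if hasattr(cells.X, "toarray") else np.asarray(cells.X)
    norm = _cp10k(X.astype(float))
    mean_a = norm[mask_a].mean(axis=0)
    mean_b = norm[mask_b].mean(axis=0)
    stat = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return rank_genes(dict(zip(cells.var_names, stat)), tie_seed=tie_seed)


def signature_overlap(signatures: dict[str, list[str]]) -> pd.DataFrame:
    """Pairwise percentage overlap 100 * |A n B| / |A u B| between signatures.

    The diagonal reports self-overlap (100).
    """
    names = list(signatures)
    if len(names) < 2:
        raise ValueError("need at least 2 signatures")
    sets = {}
    for n in names:
        s = set(signatures[n])
        if not s:
            raise ValueError(f"signature {n!r} is empty")
        sets[n] = s
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b in names:
            out.loc[a, b] = 100.0 * len(sets[a] & sets[b]) / len(sets[a] | sets[b])
    return out


def similarity_scan(
    ranking: RankedList,
    signatures: dict[str, list[str]],
    nes_min: float = 0.1,
    p_max: float = 0.001,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_overlap: int = 5,
    subset: str = "",
) -> list[SimilarityCall]:
    """Test every reference signature against one ranking; call by thresholds."""
    usable = {}
    ranked_genes = set(ranking.genes)
    flagged_low: list[str] = []
    for name, genes in signatures.items():
        if len(set(genes) & ranked_genes) < min_overlap:
            flagged_low.append(name)
        else:
            usable[name] = genes
    if not usable:
        raise ValueError("no signature overlaps the ranking sufficiently")
    results = gsea_preranked(ranking, usable, n_perm=n_perm, weight=weight, seed=seed)
    calls = []
    for r in results:
        similar = bool((r.nes > nes_min) and (r.p_nominal < p_max)) if np.isfinite(r.nes) else False
        calls.append(
            SimilarityCall(
                subset=subset,
                cluster=r.term_id,
                es=r.es,
                nes=r.nes,
                p=r.p_nominal,
                q=r.q,
                similar=similar,
                core_genes=r.leading_edge if similar else [],
                flagged=r.unstable,
            )
        )
    for name in flagged_low:
        logger.warning("signature %s overlaps the ranking by < %d genes; not called", name, min_overlap)
        calls.append(SimilarityCall(subset, name, np.nan, np.nan, np.nan, np.nan, False, [], flagged=True))
    return calls


def scan_subsets(
    cells: ad.AnnData,
    signatures: dict[str, list[str]],
    cond_a: str,
    cond_b: str,
    subsets: list[str] | None = None,
    subset_key: str = "subset",
    cond_key: str = "condition",
    nes_min: float = 0.1,
    p_max: float = 0.001,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[SimilarityCall]:
    """Run the similarity scan for every cell subset; one seed stream per subset."""
    if subsets is None:
        subsets = sorted(cells.obs[subset_key].unique())
    calls: list[SimilarityCall] = []
    for i, sub in enumerate(subsets):
        ranking = group_fold_change(
            cells, sub, cond_a, cond_b, subset_key=subset_key, cond_key=cond_key, tie_seed=seed
        )
        calls.extend(
            similarity_scan(
                ranking,
                signatures,
                nes_min=nes_min,
                p_max=p_max,
                n_perm=n_perm,
                weight=weight,
                seed=seed + i + 1,
                subset=sub,
            )
        )
    return calls


def calls_table(calls: list[SimilarityCall]) -> pd.DataFrame:
    """Flatten similarity calls into a long-format frame."""
    return pd.DataFrame(
        [
            {
                "subset": c.subset,
                "cluster": c.cluster,
                "ES": c.es,
                "NES": c.nes,
                "p": c.p,
                "q": c.q,
                "similar": c.similar,
                "core_genes": ",".join(c.core_genes),
            }
            for c in calls
        ]
    )


def core_gene_de(
    cells: ad.AnnData,
    core_genes: list[str],
    subset: str,
    cond_a: str,
    cond_b: str,
    subset_key: str = "subset",
    cond_key: str = "condition",
    p_max: float = 0.001,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene rank-sum test of the enrichment core between conditions.

    A core gene is "overexpressed" when its BH-adjusted p < ``p_max`` and its
    log2 fold change (linear CP10k group means, pseudocount 1) is positive in
    ``cond_a``.  All-zero genes are reported with p = 1.
    """
    present = [g for g in core_genes if g in set(cells.var_names)]
    if not present:
        raise ValueError("no core genes present in the matrix")
    obs = cells.obs
    in_subset = (obs[subset_key] == subset).to_numpy()
    mask_a = in_subset & (obs[cond_key] == cond_a).to_numpy()
    mask_b = in_subset & (obs[cond_key] == cond_b).to_numpy()
    X = cells.X.toarray() if hasattr(cells.X, "toarray") else np.asarray(cells.X)
    norm = _cp10k(X.astype(float))
    cols = [list(cells.var_names).index(g) for g in present]
    a = norm[np.ix_(mask_a, cols)]
    b = norm[np.ix_(mask_b, cols)]
    zero = (a.sum(axis=0) + b.sum(axis=0)) == 0
    with np.errstate(invalid="ignore"):
        res = mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p) | zero] = 1.0
    lfc = np.log2((a.mean(axis=0) + pseudocount) / (b.mean(axis=0) + pseudocount))
    adj = bh_adjust(p)
    df = pd.DataFrame(
        {"gene": present, "log2FC": lfc, "p": p, "adj_p": adj}
    )
    df["overexpressed"] = (df["adj_p"] < p_max) & (df["log2FC"] > 0)
    return df.sort_values(["adj_p", "gene"], kind="mergesort").reset_index(drop=True)
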