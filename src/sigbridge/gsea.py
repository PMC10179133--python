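"""Preranked gene-set enrichment.

Implements the weighted Kolmogorov-Smirnov running-sum enrichment score with
a gene-permutation null: hit steps are proportional to |stat|^weight
(normalized over the set), miss steps are 1/(N - set size), the enrichment
score (ES) is the running-sum value of maximal absolute deviation, and the
leading edge ("enrichment core") is the set members at or before the peak
for positive ES (at or after it for negative ES).

The null distribution is the ES of size-matched gene sets drawn uniformly
without replacement from the ranking.  The nominal p-value compares |ES|
against the magnitudes of all null draws with the +1 permutation correction,
so p is uniform under the null and bounded below by 1/(n_perm + 1); NES
divides ES by the mean |null ES| of the same sign, and FDR across terms is
Benjamini-Hochberg on nominal p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from sigbridge.genesets import GeneSetLibrary, bh_adjust

logger = logging.getLogger(__name__)

#: below this many same-sign null draws the NES/p estimates are flagged unstable
MIN_SAME_SIGN_NULL = 10


@dataclass(frozen=True)
class RankedList:
    """Genes sorted by a ranking statistic, descending, ties pre-broken."""

    genes: tuple[str, ...]
    stats: np.ndarray
    tie_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stats", np.asarray(self.stats, dtype=float))
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene IDs in ranking")
        if np.any(np.diff(self.stats) > 0):
            raise ValueError("stats must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    """Enrichment of one gene set against one ranking."""

    term_id: str
    size: int
    es: float
    nes: float
    p_nominal: float
    q: float
    leading_edge: list[str]
    peak_index: int
    n_perm: int
    seed: int
    unstable: bool = False
    no_overlap: bool = False


def rank_genes(stats: Mapping[str, float], tie_seed: int = 0) -> RankedList:
    """Sort genes by statistic descending; exact ties broken by a seeded shuffle."""
    genes = list(stats.keys())
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to rank")
    vals = np.array([stats[g] for g in genes], dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        raise ValueError(f"non-finite statistic for gene {genes[int(np.argmax(bad))]!r}")
    rng = np.random.default_rng(tie_seed)
    jitter = rng.permutation(len(genes))
    order = np.lexsort((jitter, -vals))
    return RankedList(tuple(genes[i] for i in order), vals[order], tie_seed=tie_seed)


def _hit_indicator(ranked: RankedList, geneset: Iterable[str]) -> np.ndarray:
    members = set(geneset)
    return np.fromiter((g in members for g in ranked.genes), dtype=bool, count=ranked.n)


def _es_from_hits(stats: np.ndarray, hits: np.ndarray, weight: float) -> tuple[float, np.ndarray, int]:
    n = stats.shape[0]
    n_hit = int(hits.sum())
    w = np.abs(stats) ** weight
    norm = w[hits].sum()
    if norm == 0:  # all hit statistics are exactly zero; fall back to equal steps
        w = np.ones(n)
        norm = float(n_hit)
    steps = np.where(hits, w / norm, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def enrichment_score(
    ranked: RankedList, geneset: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Weighted KS enrichment score of ``geneset`` in ``ranked``.

    Returns ``(es, running_sum, peak_index)``.  Requires at least one member
    and at least one non-member in the ranking.
    """
    hits = _hit_indicator(ranked, geneset)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranking")
    if n_hit == ranked.n:
        raise ValueError("gene set covers the whole ranking")
    return _es_from_hits(ranked.stats, hits, weight)


def leading_edge(ranked: RankedList, geneset: Iterable[str], peak_index: int, es_sign: float) -> list[str]:
    """Set members driving the ES: at/before the peak (positive ES) or at/after it."""
    members = set(geneset)
    if es_sign >= 0:
        idx = range(0, peak_index + 1)
    else:
        idx = range(peak_index, ranked.n)
    return [ranked.genes[i] for i in idx if ranked.genes[i] in members]


def _null_es(
    stats: np.ndarray, set_size: int, n_perm: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random size-matched sets (gene-permutation null)."""
    n = stats.shape[0]
    k = set_size
    # random k-subsets via partial argsort of uniform keys
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    ind = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(ind, idx, True, axis=1)
    w = np.abs(stats) ** weight
    norm = (ind * w).sum(axis=1)
    zero = norm == 0
    if zero.any():
        norm[zero] = float(k)
    steps = np.where(ind, w / norm[:, None], -1.0 / (n - k))
    if zero.any():
        steps[zero] = np.where(ind[zero], 1.0 / k, -1.0 / (n - k))
    running = np.cumsum(steps, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), peaks]


def gsea_preranked(
    ranked: RankedList,
    library: GeneSetLibrary | Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[GseaResult]:
    """Preranked GSEA of every library term against ``ranked``.

    The permutation null is shared per set size; p-values respect the
    1/(n_perm + 1) lower bound; terms with no overlap are flagged and
    excluded from the BH correction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sets = library.sets if isinstance(library, GeneSetLibrary) else {k: frozenset(v) for k, v in library.items()}
    rng = np.random.default_rng(seed)
    results: list[GseaResult] = []
    null_cache: dict[int, np.ndarray] = {}
    for term_id, genes in sets.items():
        hits = _hit_indicator(ranked, genes)
        k = int(hits.sum())
        if k == 0:
            logger.warning("term %s has no overlap with the ranking", term_id)
            results.append(
                GseaResult(term_id, 0, np.nan, np.nan, np.nan, np.nan, [], -1, n_perm, seed, no_overlap=True)
            )
            continue
        if k == ranked.n:
            raise ValueError(f"term {term_id} covers the whole ranking")
        es, _, peak = _es_from_hits(ranked.stats, hits, weight)
        if k not in null_cache:
            null_cache[k] = _null_es(ranked.stats, k, n_perm, weight, rng)
        null = null_cache[k]
        if es >= 0:
            same = null[null >= 0]
        else:
            same = null[null < 0]
        n_same = same.size
        if es == 0:
            p, nes = 1.0, 0.0
        else:
            p = (1 + int(np.sum(np.abs(null) >= abs(es)))) / (1 + n_perm)
            nes = es / float(np.mean(np.abs(same))) if n_same else np.nan
        le = leading_edge(ranked, genes, peak, es)
        results.append(
            GseaResult(
                term_id, k, es, nes, p, np.nan, le, peak, n_perm, seed,
                unstable=n_same < MIN_SAME_SIGN_NULL,
            )
        )
    scored = [r for r in results if not r.no_overlap]
    if scored:
        qs = bh_adjust([r.p_nominal for r in scored])
        for r, q in zip(scored, qs):
            r.q = float(q)
    return results
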