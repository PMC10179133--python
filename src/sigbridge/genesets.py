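"""Gene-set library construction.

Builds a signaling gene-set library from user-supplied term tables: merge and
de-duplicate terms, hypergeometric over-representation testing with
Benjamini-Hochberg FDR, kappa-based redundancy elimination, and a minimum
term-size filter.  Term tables come from any source (GO, KEGG, MSigDB exports,
hand-curated lists); no external service is queried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermRecord:
    """One named gene set (a pathway or ontology term)."""

    term_id: str
    name: str = ""
    category: str = ""
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetLibrary:
    """An ordered collection of terms over a declared gene universe."""

    terms: list[TermRecord]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate term_ids in library")
        for t in self.terms:
            if not t.genes <= self.universe:
                raise ValueError(f"term {t.term_id} has genes outside the universe")
        self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    @property
    def sets(self) -> dict[str, frozenset[str]]:
        return {t.term_id: t.genes for t in self.terms}

    @property
    def unique_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.genes
        return frozenset(out)

    @property
    def n_unique_genes(self) -> int:
        return len(self.unique_genes)


def merge_terms(tables: Iterable[TermRecord], universe: Iterable[str] | None = None) -> GeneSetLibrary:
    """Merge term records into a library, collapsing duplicate term ids.

    The library universe defaults to the union of all term genes.  A term
    repeated under the same id is kept once (first occurrence, with a logged
    warning); a term with no genes is rejected by name.
    """
    terms = list(tables)
    if not terms:
        raise ValueError("merge_terms requires at least one term")
    seen: dict[str, TermRecord] = {}
    for t in terms:
        if not t.genes:
            raise ValueError(f"term {t.term_id} has no genes")
        if t.term_id in seen:
            logger.warning("duplicate term %s dropped", t.term_id)
            continue
        seen[t.term_id] = t
    kept = list(seen.values())
    if universe is None:
        universe = frozenset().union(*(t.genes for t in kept))
    lib = GeneSetLibrary(kept, frozenset(universe))
    logger.info("merged %d terms, %d unique genes", len(lib), lib.n_unique_genes)
    return lib


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(query: Iterable[str], library: GeneSetLibrary) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each term.

    For a term of size K in a universe of size N, with a query of size n and
    overlap k, the p-value is the upper tail P(X >= k) of the hypergeometric
    distribution; q-values are Benjamini-Hochberg across terms.  Query genes
    outside the universe are dropped with a warning.  Rows sorted by p.
    """
    query = set(query)
    outside = query - library.universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
    query &= library.universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    N = len(library.universe)
    n = len(query)
    rows = []
    for t in library.terms:
        K = t.size
        k = len(t.genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((t.term_id, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def kappa_similarity(a: frozenset[str], b: frozenset[str], n_universe: int) -> float:
    """Cohen's kappa between two gene sets as membership indicators.

    The 2x2 agreement table over the universe is (in both, only a, only b,
    in neither); kappa = (observed - chance agreement) / (1 - chance).
    """
    i = len(a & b)
    oa = len(a) - i
    ob = len(b) - i
    d = n_universe - i - oa - ob
    if d < 0:
        raise ValueError("sets larger than the universe")
    po = (i + d) / n_universe
    pe = ((i + oa) * (i + ob) + (ob + d) * (oa + d)) / n_universe**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def redundancy_filter(
    library: GeneSetLibrary,
    cutoff: float = 0.5,
    pvalues: Mapping[str, float] | None = None,
) -> tuple[GeneSetLibrary, list[tuple[str, str, float]]]:
    """Greedy elimination of redundant terms by kappa similarity.

    Terms are visited in order of enrichment p-value ascending (or size
    descending if no p-values are supplied), ties broken by term_id; a term is
    dropped when its kappa similarity to an already-retained term exceeds
    ``cutoff``.  Returns the filtered library and a drop log of
    ``(dropped_id, kept_id, kappa)`` triples.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    if not library.terms:
        raise ValueError("library is empty")
    if pvalues is not None:
        order = sorted(library.terms, key=lambda t: (pvalues.get(t.term_id, 1.0), t.term_id))
    else:
        order = sorted(library.terms, key=lambda t: (-t.size, t.term_id))
    n_universe = len(library.universe)
    retained: list[TermRecord] = []
    dropped: list[tuple[str, str, float]] = []
    for t in order:
        hit = None
        for r in retained:
            kap = kappa_similarity(t.genes, r.genes, n_universe)
            if kap > cutoff:
                hit = (t.term_id, r.term_id, kap)
                break
        if hit is None:
            retained.append(t)
        else:
            dropped.append(hit)
    # restore the library's original term order among retained terms
    keep_ids = {t.term_id for t in retained}
    kept = [t for t in library.terms if t.term_id in keep_ids]
    return GeneSetLibrary(kept, library.universe), dropped


def size_filter(library: GeneSetLibrary, min_size: int = 10) -> GeneSetLibrary:
    """Drop terms with fewer than ``min_size`` genes (inclusive bound)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [t for t in library.terms if t.size >= min_size]
    if not kept:
        logger.warning("size_filter removed every term")
    return GeneSetLibrary(kept, library.universe)


def build_library(
    terms: Iterable[TermRecord],
    query: Iterable[str] | None = None,
    fdr: float = 0.05,
    redundancy_cutoff: float = 0.5,
    min_size: int = 10,
    universe: Iterable[str] | None = None,
) -> tuple[GeneSetLibrary, pd.DataFrame | None]:
    """Full library pipeline: merge -> enrich -> FDR filter -> redundancy -> size.

    When ``query`` is given, terms are first filtered to q < ``fdr`` and the
    redundancy pass is ordered by enrichment p; otherwise enrichment is
    skipped and the redundancy pass is ordered by size.  Returns the final
    library and the enrichment table (or None).
    """
    lib = merge_terms(terms, universe=universe)
    table = None
    pvals = None
    if query is not None:
        table = hypergeometric_enrichment(query, lib)
        sig = set(table.loc[table["q"] < fdr, "term_id"])
        lib = GeneSetLibrary([t for t in lib.terms if t.term_id in sig], lib.universe)
        if not lib.terms:
            logger.warning("no terms pass FDR %.3g", fdr)
            return lib, table
        pvals = dict(zip(table["term_id"], table["p"]))
    lib, _ = redundancy_filter(lib, cutoff=redundancy_cutoff, pvalues=pvals)
    lib = size_filter(lib, min_size=min_size)
    return lib, table


def rename_terms(library: GeneSetLibrary, mapping: Mapping[str, str]) -> GeneSetLibrary:
    """Return a library with term ids renamed via ``mapping`` (missing ids kept)."""
    return GeneSetLibrary(
        [replace(t, term_id=mapping.get(t.term_id, t.term_id)) for t in library.terms],
        library.universe,
    )
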