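"""Readers and writers for the standard text formats the pipeline uses.

GMT gene-set libraries, RNK preranked lists, genes x samples TSV matrices
with sample metadata TSV, and MatrixMarket triplet count directories with
features/barcodes sidecars (10x layout, gzip-compressed sidecars accepted).
All writers are deterministic: sorted keys where order is not meaningful and
floats serialized with 6 significant digits.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from sigbridge.containers import CountMatrix, ExpressionMatrix
from sigbridge.genesets import GeneSetLibrary, TermRecord
from sigbridge.gsea import RankedList

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


# ---------------------------------------------------------------- GMT / RNK


def read_gmt(path) -> GeneSetLibrary:
    """Parse a GMT file (term, description, genes...) into a library."""
    terms: list[TermRecord] = []
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, desc, *genes = fields
            genes = [g for g in genes if g]
            terms.append(TermRecord(term_id=term_id, name=desc, genes=frozenset(genes)))
    if not terms:
        raise ValueError(f"{path}: empty GMT file")
    universe = frozenset().union(*(t.genes for t in terms))
    return GeneSetLibrary(terms, universe)


def write_gmt(library: GeneSetLibrary | Mapping[str, list[str]], path) -> None:
    """Write a library (or a plain name -> genes mapping) as GMT."""
    with open(path, "w") as fh:
        if isinstance(library, GeneSetLibrary):
            items = [(t.term_id, t.name, sorted(t.genes)) for t in library.terms]
        else:
            items = [(name, "", list(genes)) for name, genes in library.items()]
        for term_id, desc, genes in items:
            fh.write("\t".join([term_id, desc or term_id] + list(genes)) + "\n")


def read_rnk(path) -> dict[str, float]:
    """Two-column gene/statistic TSV (RNK convention)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["gene", "stat"])
    return dict(zip(df["gene"].astype(str), df["stat"].astype(float)))


def write_rnk(ranked: RankedList | Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        if isinstance(ranked, RankedList):
            pairs = zip(ranked.genes, ranked.stats)
        else:
            pairs = sorted(ranked.items(), key=lambda kv: (-kv[1], kv[0]))
        for gene, stat in pairs:
            fh.write(f"{gene}\t{FLOAT_FMT % stat}\n")


# ---------------------------------------------------------------- matrices


def read_matrix_tsv(path, meta_path=None, counts: bool = False) -> ExpressionMatrix:
    """Genes x samples TSV (header row of sample IDs) -> samples x genes matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.T
    values.index.name = None
    values.columns.name = None
    if not counts:
        values = values.astype(float)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    cls = CountMatrix if counts else ExpressionMatrix
    return cls(values, meta)


def write_matrix_tsv(matrix: ExpressionMatrix, path, meta_path=None) -> None:
    """Write samples x genes values as a genes x samples TSV (and metadata TSV)."""
    matrix.values.T.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if meta_path is not None:
        matrix.meta.to_csv(meta_path, sep="\t", float_format=FLOAT_FMT)


def _read_sidecar(dirpath: Path, names: tuple[str, ...]) -> list[str]:
    for name in names:
        for suffix in ("", ".gz"):
            p = dirpath / (name + suffix)
            if p.exists():
                with _open_text(p) as fh:
                    return [line.rstrip("\r\n").split("\t")[0] for line in fh if line.strip()]
    raise FileNotFoundError(f"none of {names} found in {dirpath}")


def _dedupe(ids: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    dups = 0
    for x in ids:
        if x in seen:
            seen[x] += 1
            out.append(f"{x}-{seen[x]}")
            dups += 1
        else:
            seen[x] = 0
            out.append(x)
    if dups:
        logger.warning("%d duplicate %s IDs suffixed deterministically", dups, what)
    return out


def read_counts_mtx(dirpath, obs_path=None) -> ad.AnnData:
    """Read a 10x-style triplet directory (matrix.mtx + features/barcodes).

    The MatrixMarket matrix is genes x cells; the returned AnnData is
    cells x genes with integer counts preserved exactly.  Optional per-cell
    metadata TSV (indexed by barcode) is merged into ``obs``.
    """
    dirpath = Path(dirpath)
    mtx = None
    for name in ("matrix.mtx", "matrix.mtx.gz"):
        if (dirpath / name).exists():
            mtx = spio.mmread(str(dirpath / name))
            break
    if mtx is None:
        raise FileNotFoundError(f"no matrix.mtx in {dirpath}")
    features = _dedupe(_read_sidecar(dirpath, ("features.tsv", "genes.tsv")), "feature")
    barcodes = _dedupe(_read_sidecar(dirpath, ("barcodes.tsv",)), "barcode")
    X = sparse.csr_matrix(mtx.T)
    if X.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"{dirpath}: matrix shape {mtx.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    adata = ad.AnnData(
        X=X, obs=pd.DataFrame(index=barcodes), var=pd.DataFrame(index=features)
    )
    if obs_path is not None:
        meta = pd.read_csv(obs_path, sep="\t", index_col=0)
        adata.obs = adata.obs.join(meta)
    return adata


def write_counts_mtx(adata: ad.AnnData, dirpath) -> None:
    """Write cells x genes counts as MatrixMarket triplet + sidecars + obs TSV."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(str(dirpath / "matrix.mtx"), sparse.coo_matrix(X.T), field="integer")
    (dirpath / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
    (dirpath / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    if len(adata.obs.columns):
        adata.obs.to_csv(dirpath / "metadata.tsv", sep="\t", float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Deterministic long-format TSV writer (6 significant digits)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
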