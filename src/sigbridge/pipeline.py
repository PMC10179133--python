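"""End-to-end pipeline: bulk clustering arm -> bridge scan -> survival.

``run_pipeline`` chains the stages on synthetic data (or user-supplied
matrices), writing every intermediate as deterministic TSV/GMT artifacts plus
a JSON manifest recording the seed and parameters.  Each stochastic stage
receives a seed derived deterministically from the global seed and the stage
name, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from sigbridge import __version__
from sigbridge.bridge import calls_table, core_gene_de, scan_subsets, signature_overlap
from sigbridge.cluster import conserved_markers, mnn_correct, preprocess_bulk, reduce_and_cluster
from sigbridge.io import write_gmt, write_matrix_tsv, write_table
from sigbridge.simulate import SimConfig, simulate_bulk_cohort, simulate_sc_counts
from sigbridge.sc import normalize_cells, qc_filter
from sigbridge.surv import km_by_group, logrank_test, pairwise_logrank

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Global seed plus per-stage parameter blocks for ``run_pipeline``."""

    seed: int = 0
    outdir: str = "sigbridge_run"
    sim: SimConfig | None = None
    n_pcs: int = 20
    k_nn: int = 20
    resolution: float = 0.5
    mnn_k: int = 20
    fc_min: float = 0.25
    p_max_markers: float = 0.001
    top_k: int = 20
    nes_min: float = 0.1
    p_max_similarity: float = 0.001
    n_perm: int = 1000
    gsea_weight: float = 1.0
    qc_min_genes: int = 1000
    qc_max_mito: float = 0.10
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Run the synthetic end-to-end analysis and write artifacts.

    Stages: simulate bulk cohort -> preprocess (signature restriction) ->
    MNN batch correction -> SNN/Louvain clustering -> conserved-marker
    signatures -> KM/log-rank survival by cluster -> simulate single-cell
    counts with the largest cluster's signature planted in the target subset
    -> QC -> normalization -> similarity scan -> enrichment-core DE.
    Returns a summary dict (also written as ``manifest.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim or SimConfig(seed=stage_seed(config.seed, "simulate"))

    cohort = simulate_bulk_cohort(sim)
    write_matrix_tsv(cohort.expr, out / "bulk_expr.tsv", out / "bulk_meta.tsv")
    write_table(cohort.survival, out / "bulk_survival.tsv")

    pre = preprocess_bulk(cohort.expr, cohort.signature_space)
    corrected = mnn_correct(pre, "batch", k=config.mnn_k)
    corrected.layers = pre.layers  # marker stats stay on the uncorrected log2 layer
    assign, _ = reduce_and_cluster(
        corrected,
        n_pcs=config.n_pcs,
        k_nn=config.k_nn,
        resolution=config.resolution,
        seed=stage_seed(config.seed, "cluster"),
    )
    assign.labels.rename("cluster").to_frame().to_csv(out / "clusters.tsv", sep="\t")

    markers, signatures = conserved_markers(
        corrected,
        assign,
        group_key="batch",
        fc_min=config.fc_min,
        p_max=config.p_max_markers,
        top_k=config.top_k,
    )
    write_table(markers, out / "markers.tsv")
    signatures = {k: v for k, v in signatures.items() if v}
    write_gmt(signatures, out / "signatures.gmt")
    if len(signatures) >= 2:
        write_table(signature_overlap(signatures), out / "signature_overlap.tsv", index=True)

    surv_df = cohort.survival.assign(group=assign.labels.loc[cohort.survival["sample"]].to_numpy())
    curves = km_by_group(surv_df)
    km_rows = [
        {"group": g, "n": c.n, "events": c.n_events, "median_months": c.median}
        for g, c in curves.items()
    ]
    write_table(pd.DataFrame(km_rows), out / "km_summary.tsv")
    lr = logrank_test(surv_df)
    write_table(pairwise_logrank(surv_df), out / "logrank_pairwise.tsv")

    # plant the signature of the largest cluster into the target subset
    planted_cluster = max(signatures, key=lambda k: (len(signatures[k]), k))
    cells = simulate_sc_counts(
        dataclasses.replace(sim, seed=stage_seed(config.seed, "sc")),
        signature_genes=signatures[planted_cluster],
    )
    cells, qc_report = qc_filter(cells, min_genes=config.qc_min_genes, max_mito=config.qc_max_mito)
    cells = normalize_cells(cells)
    calls = scan_subsets(
        cells,
        signatures,
        cond_a=sim.case_condition,
        cond_b=[c for c in sim.conditions if c != sim.case_condition][0],
        nes_min=config.nes_min,
        p_max=config.p_max_similarity,
        n_perm=config.n_perm,
        weight=config.gsea_weight,
        seed=stage_seed(config.seed, "scan"),
    )
    write_table(calls_table(calls), out / "similarity_calls.tsv")
    hits = [c for c in calls if c.similar]
    core_tables = []
    for c in hits:
        de = core_gene_de(
            cells, c.core_genes, c.subset, sim.case_condition,
            [x for x in sim.conditions if x != sim.case_condition][0],
        )
        de.insert(0, "cluster", c.cluster)
        de.insert(0, "subset", c.subset)
        core_tables.append(de)
    if core_tables:
        write_table(pd.concat(core_tables, ignore_index=True), out / "core_gene_de.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate", "cluster", "sc", "scan")},
        "parameters": {k: v for k, v in config.to_dict().items() if k != "sim"},
        "n_clusters": assign.n_clusters,
        "planted_cluster": planted_cluster,
        "qc": qc_report,
        "logrank": lr,
        "similar_calls": [(c.subset, c.cluster) for c in hits],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
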