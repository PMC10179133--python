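"""Synthetic cohorts with planted ground truth.

Three generators emulate the data shapes the analysis consumes:

* :func:`simulate_bulk_cohort` — a ~500-sample bulk expression cohort
  (FPKM-like, log-normal on the log2 scale) with K planted clusters defined
  by disjoint signature-gene blocks, additive batch structure on a random
  30% of genes, and cluster-dependent exponential progression-free survival.
* :func:`simulate_sc_counts` — a two-condition PBMC-like negative-binomial
  count matrix with B-cell subsets (marker blocks) and, optionally, a planted
  up-shift of a supplied signature in one subset of the case condition.
* :func:`simulate_tissue_counts` — a small tissue count matrix with age
  metadata spanning the young (<30), middle (30-50) and old (>50) groups and
  planted differentially expressed genes in the old group.

All generators are deterministic given ``SimConfig.seed`` (each consumes an
independent seeded stream, so the three outputs do not interact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from sigbridge.containers import CountMatrix, ExpressionMatrix

_LN2 = np.log(2.0)


@dataclass
class SimConfig:
    """Parameters of the three synthetic generators (see module docstring).

    Effect sizes are log2 fold changes; survival medians are months;
    dispersions are negative-binomial (variance = mu + disp * mu^2).
    """

    seed: int = 0
    n_genes: int = 2000

    # --- bulk cohort ---
    n_samples: int = 500
    n_clusters: int = 5
    signature_space_size: int = 626
    genes_per_cluster_signature: int = 20
    bulk_log2fc: float = 1.0
    bulk_noise_sd: float = 0.5
    n_batches: int = 2
    batch_shift: float = 0.8
    batch_genes_frac: float = 0.3
    cluster_median_pfs_months: tuple[float, ...] = (10.0, 12.0, 13.0, 16.0, 14.0)
    censor_horizon_months: float = 60.0
    dropout_median_months: float = 120.0

    # --- single-cell counts ---
    subsets: tuple[str, ...] = ("Trans", "Naive", "M-mem", "DN")
    conditions: tuple[str, ...] = ("pSS", "HC")
    cells_per_group: int = 150
    subset_marker_genes: int = 30
    subset_marker_log2fc: float = 2.0
    sc_dispersion: float = 0.5
    sc_depth: float = 6000.0
    sc_depth_sigma: float = 0.25
    sc_signature_log2fc: float = 0.8
    target_subset: str = "Naive"
    case_condition: str = "pSS"
    n_donors_per_condition: int = 5
    low_quality_frac: float = 0.05
    low_quality_depth_factor: float = 0.08
    mito_range: tuple[float, float] = (0.01, 0.08)
    high_mito_frac: float = 0.05
    high_mito_range: tuple[float, float] = (0.10, 0.30)

    # --- tissue counts ---
    n_per_age_group: int = 10
    tissue_dispersion: float = 0.1
    n_deg: int = 50
    deg_log2fc: float = 2.0

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass
class BulkCohort:
    """Output of :func:`simulate_bulk_cohort`."""

    expr: ExpressionMatrix
    labels: pd.Series  # true cluster per sample, "C1".."CK"
    survival: pd.DataFrame  # sample, time_months, event, group
    signatures: dict[str, list[str]]  # planted signature genes per cluster
    signature_space: list[str]  # the gene set handed to clustering
    batch_genes: list[str] = field(default_factory=list)


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB2 draws with variance mu + dispersion * mu^2 (Poisson when disp -> 0)."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_bulk_cohort(config: SimConfig) -> BulkCohort:
    """Generate the bulk cohort with planted signature-defined clusters."""
    K = config.n_clusters
    if K < 1:
        raise ValueError("n_clusters must be >= 1")
    if K > config.n_samples:
        raise ValueError("more clusters than samples")
    if config.bulk_log2fc < 0:
        raise ValueError("bulk_log2fc must be non-negative (planted shifts are up-shifts)")
    need = K * config.genes_per_cluster_signature
    if need > config.signature_space_size or config.signature_space_size > config.n_genes:
        raise ValueError("signature blocks must fit inside the signature space and gene universe")
    if len(config.cluster_median_pfs_months) < K:
        raise ValueError("need a median PFS per cluster")

    rng = np.random.default_rng([config.seed, 1])
    genes = config.gene_names()
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    sig_space = genes[: config.signature_space_size]
    g = config.genes_per_cluster_signature
    signatures = {f"C{c + 1}": sig_space[c * g : (c + 1) * g] for c in range(K)}

    # per-gene baseline on the log2 scale; signature-space genes sit higher so
    # the +1 pseudocount downstream barely perturbs planted shifts
    base = rng.uniform(2.0, 8.0, size=config.n_genes)
    base[: config.signature_space_size] = rng.uniform(4.0, 8.0, size=config.signature_space_size)

    cluster_idx = rng.permutation(np.arange(config.n_samples) % K)
    labels = pd.Series([f"C{c + 1}" for c in cluster_idx], index=samples, name="cluster")
    batch = np.array([f"B{i % config.n_batches + 1}" for i in range(config.n_samples)])

    shift = np.zeros((config.n_samples, config.n_genes))
    gene_pos = {gname: j for j, gname in enumerate(genes)}
    for c in range(K):
        cols = [gene_pos[gname] for gname in signatures[f"C{c + 1}"]]
        shift[np.ix_(cluster_idx == c, cols)] += config.bulk_log2fc

    n_batch_genes = int(round(config.batch_genes_frac * config.n_genes))
    batch_cols = rng.choice(config.n_genes, size=n_batch_genes, replace=False)
    for b in range(1, config.n_batches):
        rows = batch == f"B{b + 1}"
        shift[np.ix_(rows, batch_cols)] += config.batch_shift * b

    logval = base[None, :] + shift + rng.normal(0.0, config.bulk_noise_sd, size=shift.shape)
    fpkm = 2.0**logval

    medians = np.asarray(config.cluster_median_pfs_months[:K], dtype=float)
    t_prog = rng.exponential(medians[cluster_idx] / _LN2)
    t_drop = rng.exponential(config.dropout_median_months / _LN2, size=config.n_samples)
    t_cens = np.minimum(t_drop, config.censor_horizon_months)
    time = np.minimum(t_prog, t_cens)
    event = (t_prog <= t_cens).astype(int)

    meta = pd.DataFrame(
        {
            "batch": batch,
            "coo": rng.choice(["GCB", "ABC", "unclassified"], size=config.n_samples, p=[0.5, 0.4, 0.1]),
            "ipi": rng.choice(["low", "low-int", "high-int", "high"], size=config.n_samples),
            "pfs_months": time,
            "pfs_event": event,
        },
        index=samples,
    )
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=samples, columns=genes), meta)
    survival = pd.DataFrame(
        {"sample": samples, "time_months": time, "event": event, "group": labels.to_numpy()}
    )
    return BulkCohort(expr, labels, survival, signatures, sig_space, [genes[j] for j in sorted(batch_cols)])


def simulate_sc_counts(config: SimConfig, signature_genes: list[str] | None = None) -> ad.AnnData:
    """Generate the two-condition single-cell count matrix.

    When ``signature_genes`` is given and ``sc_signature_log2fc`` > 0, those
    genes are up-shifted in the ``target_subset`` cells of the
    ``case_condition`` only — the planted "bridge" signal.
    """
    if config.sc_dispersion <= 0:
        raise ValueError("sc_dispersion must be positive")
    if config.sc_signature_log2fc < 0:
        raise ValueError("sc_signature_log2fc must be non-negative (planted shifts are up-shifts)")
    if len(config.conditions) != 2:
        raise ValueError("exactly two conditions required")
    if config.target_subset not in config.subsets:
        raise ValueError(f"target subset {config.target_subset!r} not among subsets")
    if config.case_condition not in config.conditions:
        raise ValueError(f"case condition {config.case_condition!r} not among conditions")

    rng = np.random.default_rng([config.seed, 2])
    genes = config.gene_names()
    n_sub, n_cond = len(config.subsets), len(config.conditions)
    n_cells = n_sub * n_cond * config.cells_per_group

    # subset marker blocks live at the tail of the gene list, away from any
    # planted signature (bulk signatures come from the head of the universe)
    m = config.subset_marker_genes
    markers: dict[str, list[str]] = {}
    for s, sub in enumerate(config.subsets):
        lo = config.n_genes - (s + 1) * m
        if lo < 0:
            raise ValueError("marker blocks exceed the gene universe; increase n_genes")
        markers[sub] = genes[lo : config.n_genes - s * m]
    if signature_genes:
        clash = set(signature_genes) & {g for ms in markers.values() for g in ms}
        if clash:
            raise ValueError(f"planted signature overlaps subset marker blocks: {sorted(clash)[:5]}")

    subset = np.repeat(list(config.subsets), n_cond * config.cells_per_group)
    condition = np.tile(np.repeat(list(config.conditions), config.cells_per_group), n_sub)

    weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    lfc = np.zeros((n_cells, config.n_genes))
    gene_pos = {gname: j for j, gname in enumerate(genes)}
    for sub in config.subsets:
        cols = [gene_pos[gname] for gname in markers[sub]]
        lfc[np.ix_(subset == sub, cols)] += config.subset_marker_log2fc
    planted: list[str] = []
    if signature_genes and config.sc_signature_log2fc > 0:
        planted = [gname for gname in signature_genes if gname in gene_pos]
        cols = [gene_pos[gname] for gname in planted]
        rows = (subset == config.target_subset) & (condition == config.case_condition)
        lfc[np.ix_(rows, cols)] += config.sc_signature_log2fc

    rel = weights[None, :] * 2.0**lfc
    rel /= rel.sum(axis=1, keepdims=True)

    depth = rng.lognormal(np.log(config.sc_depth), config.sc_depth_sigma, size=n_cells)
    low_quality = rng.random(n_cells) < config.low_quality_frac
    depth[low_quality] *= config.low_quality_depth_factor

    counts = _nb_draws(rng, rel * depth[:, None], config.sc_dispersion)

    high_mito = rng.random(n_cells) < config.high_mito_frac
    mito = rng.uniform(*config.mito_range, size=n_cells)
    mito[high_mito] = rng.uniform(*config.high_mito_range, size=int(high_mito.sum()))

    obs = pd.DataFrame(
        {
            "subset": subset,
            "condition": condition,
            "donor": [
                f"{c}-D{i % config.n_donors_per_condition + 1}" for i, c in enumerate(condition)
            ],
            "mito_frac": mito,
            "low_quality": low_quality,
            "high_mito": high_mito,
            "n_genes_detected": (counts > 0).sum(axis=1),
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(X=counts.astype(np.float64), obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["truth"] = {
        "markers": markers,
        "planted_signature": planted,
        "target_subset": config.target_subset,
        "case_condition": config.case_condition,
        "planted_log2fc": config.sc_signature_log2fc if planted else 0.0,
    }
    return adata


@dataclass
class TissueCounts:
    """Output of :func:`simulate_tissue_counts`."""

    counts: CountMatrix
    deg_genes: list[str]  # planted up-regulated genes in the old-aged group


def simulate_tissue_counts(config: SimConfig) -> TissueCounts:
    """Generate tissue counts with planted DEGs between old-aged and other samples."""
    if config.n_per_age_group < 2:
        raise ValueError("need at least 2 samples per age group")
    if config.tissue_dispersion <= 0:
        raise ValueError("tissue_dispersion must be positive")
    rng = np.random.default_rng([config.seed, 3])
    genes = config.gene_names()
    n = 3 * config.n_per_age_group
    ages = np.concatenate(
        [
            rng.uniform(18.0, 29.5, config.n_per_age_group),
            rng.uniform(30.0, 50.0, config.n_per_age_group),
            rng.uniform(51.0, 80.0, config.n_per_age_group),
        ]
    )
    group = np.repeat(["young", "middle", "old"], config.n_per_age_group)
    samples = [f"T{i:03d}" for i in range(n)]

    base = rng.lognormal(np.log(100.0), 1.0, size=config.n_genes)
    deg_cols = rng.choice(config.n_genes, size=config.n_deg, replace=False) if config.n_deg else np.array([], int)
    sf = rng.lognormal(0.0, 0.25, size=n)
    lfc = np.zeros((n, config.n_genes))
    lfc[np.ix_(group == "old", deg_cols)] = config.deg_log2fc
    mu = sf[:, None] * base[None, :] * 2.0**lfc
    counts = _nb_draws(rng, mu, config.tissue_dispersion)

    meta = pd.DataFrame(
        {"condition": "pSS", "age_years": ages, "age_group": group}, index=samples
    )
    cm = CountMatrix(pd.DataFrame(counts, index=samples, columns=genes), meta)
    return TissueCounts(cm, sorted(genes[j] for j in deg_cols))
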