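"""Differential expression for bulk tissue counts.

A simplified negative-binomial Wald test: per-sample size factors by the
median-of-ratios rule, per-gene NB2 dispersion by method of moments shrunk
halfway (in log space) toward a mean-dispersion trend, the log2 fold change
of group means of normalized counts, a delta-method standard error, and a
normal-reference Wald p with Benjamini-Hochberg adjustment.  DEG calling
follows adjusted p < 0.05 and |log2FC| >= 1 by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from sigbridge.containers import CountMatrix
from sigbridge.genesets import bh_adjust

logger = logging.getLogger(__name__)

_MIN_DISP = 1e-8


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (samples x genes counts).

    factor_j = median over genes (nonzero in every sample) of
    count_gj / geometric-mean_g.  Falls back to upper-quartile normalization
    (scaled to geometric mean 1) when no gene is expressed everywhere.
    """
    df = counts.values if isinstance(counts, CountMatrix) else counts
    X = df.to_numpy(dtype=float)
    always_on = (X > 0).all(axis=0)
    if always_on.any():
        logmean = np.log(X[:, always_on]).mean(axis=0)
        ratios = np.log(X[:, always_on]) - logmean[None, :]
        sf = np.exp(np.median(ratios, axis=1))
    else:
        logger.warning("no gene nonzero in all samples; using upper-quartile factors")
        uq = np.array([np.percentile(row[row > 0], 75) if (row > 0).any() else 1.0 for row in X])
        sf = uq / np.exp(np.mean(np.log(uq)))
    return pd.Series(sf, index=df.index, name="size_factor")


def vst_layer(counts: CountMatrix | pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """Depth-stabilized layer log2(count / size_factor + 1)."""
    df = counts.values if isinstance(counts, CountMatrix) else counts
    if sf is None:
        sf = size_factors(df)
    return np.log2(df.div(sf, axis=0) + 1.0)


def _dispersion_estimates(q: np.ndarray, groups: list[np.ndarray], inv_s_mean: float) -> np.ndarray:
    """MoM NB2 dispersion per gene, shrunk 50% in log space toward a 1/mu trend."""
    mu = q.mean(axis=0)
    resid_ss = np.zeros(q.shape[1])
    dof = 0
    for g in groups:
        sub = q[g]
        resid_ss += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
        dof += len(g) - 1
    var = resid_ss / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu * inv_s_mean) / mu**2
    raw = np.where(np.isfinite(raw), raw, _MIN_DISP)
    raw = np.clip(raw, _MIN_DISP, None)
    # trend alpha(mu) = a/mu + b fitted by least squares on informative genes
    ok = (mu > 0) & (raw > _MIN_DISP * 10)
    if ok.sum() >= 10:
        A = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a, b = coef
        with np.errstate(divide="ignore"):
            trend = np.clip(a / np.where(mu > 0, mu, np.inf) + b, _MIN_DISP, None)
    else:
        trend = np.full_like(raw, max(np.median(raw), _MIN_DISP))
    return np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))


def nb_wald_de(
    counts: CountMatrix,
    group_key: str,
    level_a: str,
    level_b: str,
    fc_min_log2: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Negative-binomial Wald differential expression, ``level_a`` vs ``level_b``.

    Returns a frame with columns gene, log2FC, SE, wald, p, adj_p, is_deg;
    is_deg = (adj_p < ``alpha``) and (|log2FC| >= ``fc_min_log2``).  All-zero
    genes report p = 1, log2FC = 0.
    """
    meta = counts.meta
    ga = (meta[group_key].astype(str) == level_a).to_numpy()
    gb = (meta[group_key].astype(str) == level_b).to_numpy()
    if ga.sum() < 2 or gb.sum() < 2:
        raise ValueError("need at least 2 samples per level")
    X = counts.values.to_numpy(dtype=float)
    sf = size_factors(counts).to_numpy()
    q = X / sf[:, None]
    sub = np.flatnonzero(ga | gb)
    groups_local = [np.flatnonzero(ga[sub]), np.flatnonzero(gb[sub])]
    disp = _dispersion_estimates(q[sub], groups_local, float(np.mean(1.0 / sf[sub])))

    mu_a = q[ga].mean(axis=0)
    mu_b = q[gb].mean(axis=0)
    zero = (mu_a == 0) & (mu_b == 0)
    # an eighth of a normalized count guards the log ratio for one-sided zeros
    pc = np.where((mu_a == 0) | (mu_b == 0), 0.125, 0.0)
    lfc = np.log2((mu_a + pc) / np.where(mu_b + pc > 0, mu_b + pc, 1.0))
    lfc[zero] = 0.0

    def _var_mean(mask: np.ndarray, mu: np.ndarray) -> np.ndarray:
        n = mask.sum()
        inv_s = 1.0 / sf[mask]
        return (mu[None, :] * inv_s[:, None] + disp[None, :] * mu[None, :] ** 2).sum(axis=0) / n**2

    va = _var_mean(ga, mu_a)
    vb = _var_mean(gb, mu_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            va / np.maximum(mu_a + pc, 1e-300) ** 2 + vb / np.maximum(mu_b + pc, 1e-300) ** 2
        ) / np.log(2.0)
        wald = lfc / se
    wald = np.where(np.isfinite(wald), wald, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p[zero] = 1.0
    adj = bh_adjust(p)
    df = pd.DataFrame(
        {
            "gene": counts.values.columns,
            "baseMean": q.mean(axis=0),
            "log2FC": lfc,
            "SE": se,
            "wald": wald,
            "p": p,
            "adj_p": adj,
        }
    )
    df["is_deg"] = (df["adj_p"] < alpha) & (df["log2FC"].abs() >= fc_min_log2)
    return df


def age_group_assign(age_years) -> np.ndarray | str:
    """Map age in years to young (<30), middle (30-50 inclusive), old (>50)."""
    arr = np.asarray(age_years, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative age")
    out = np.where(arr < 30, "young", np.where(arr <= 50, "middle", "old"))
    if np.isscalar(age_years) or arr.ndim == 0:
        return str(out)
    return out


def correlate_genes(
    layer: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    method: str = "spearman",
    rho_min: float = 0.3,
    p_gate: float = 0.05,
) -> dict:
    """Correlation between two genes across samples, with a 'correlated' flag.

    Flag raised when |rho| > ``rho_min`` and p < ``p_gate``.
    """
    a = layer[gene_a].to_numpy(dtype=float)
    b = layer[gene_b].to_numpy(dtype=float)
    if len(a) < 5:
        raise ValueError("need at least 5 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant expression vector")
    if method == "spearman":
        rho, p = stats.spearmanr(a, b)
    elif method == "pearson":
        rho, p = stats.pearsonr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "gene_a": gene_a,
        "gene_b": gene_b,
        "method": method,
        "rho": float(rho),
        "p": float(p),
        "correlated": bool(abs(rho) > rho_min and p < p_gate),
    }
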