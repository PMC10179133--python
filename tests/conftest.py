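import numpy as np
import pandas as pd
import pytest

from sigbridge.containers import ExpressionMatrix
from sigbridge.simulate import SimConfig, simulate_bulk_cohort, simulate_sc_counts, simulate_tissue_counts


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced bulk cohort (150 samples, 3 clusters) for unit tests."""
    cfg = SimConfig(
        seed=101,
        n_samples=150,
        n_clusters=3,
        n_genes=500,
        signature_space_size=200,
        cluster_median_pfs_months=(10.0, 13.0, 16.0),
    )
    return cfg, simulate_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def sc_data():
    """A reduced two-condition single-cell dataset with a planted signature."""
    cfg = SimConfig(seed=202, cells_per_group=100, low_quality_frac=0.1)
    planted = [f"G{i:05d}" for i in range(20)]
    return cfg, planted, simulate_sc_counts(cfg, signature_genes=planted)


@pytest.fixture(scope="session")
def tissue_data():
    cfg = SimConfig(seed=303)
    return cfg, simulate_tissue_counts(cfg)


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs as an ExpressionMatrix."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 1.0, size=(40, 30))
    b = rng.normal(10.0, 1.0, size=(40, 30))
    X = np.vstack([a, b])
    idx = [f"s{i:03d}" for i in range(80)]
    em = ExpressionMatrix(
        pd.DataFrame(X, index=idx, columns=[f"g{j}" for j in range(30)]),
        pd.DataFrame({"truth": ["A"] * 40 + ["B"] * 40}, index=idx),
    )
    return em
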