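"""In-memory containers shared across the pipeline.

Bulk data travel as :class:`ExpressionMatrix` (a samples x genes values frame
plus an aligned per-sample metadata frame).  Single-cell data travel as
:class:`anndata.AnnData` with raw counts in ``X`` and the normalized layer in
``layers["lognorm"]``; gene symbols are the join key everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with aligned sample metadata.

    Parameters
    ----------
    values
        Expression frame, one row per sample, one column per gene.  Units are
        whatever the producing step defines (FPKM-like on input, log2 or
        z-scaled after preprocessing).
    meta
        Per-sample metadata (batch/project, subtype, survival fields, ...),
        indexed like ``values``.
    layers
        Optional named alternative value frames aligned with ``values``
        (e.g. the unscaled log2 layer kept alongside the z-scaled one).
    """

    values: pd.DataFrame
    meta: pd.DataFrame | None = None
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.values.index)
        else:
            if not self.meta.index.equals(self.values.index):
                # allow same set in different order; realign
                if set(self.meta.index) != set(self.values.index):
                    raise ValueError("metadata rows do not align 1:1 with samples")
                self.meta = self.meta.loc[self.values.index]
        for name, layer in self.layers.items():
            if layer.shape != self.values.shape:
                raise ValueError(f"layer {name!r} is not aligned with values")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.columns]
        return ExpressionMatrix(
            self.values[genes].copy(),
            self.meta.copy(),
            {k: v[genes].copy() for k, v in self.layers.items()},
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.meta.copy(), {k: v.copy() for k, v in self.layers.items()}
        )


@dataclass
class CountMatrix(ExpressionMatrix):
    """Samples x genes integer counts (bulk tissue sequencing)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not (vals == vals.round()).all():
            raise ValueError("counts must be integers")
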