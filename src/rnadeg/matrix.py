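"""Gene-by-sample count matrices.

The count matrix is the substrate of filtering, normalization and
differential-expression testing.  Counts are integer reads per gene and
sample; library sizes default to the column totals and are deliberately
*frozen* at construction so that gene filtering does not silently change
the CPM scale (see :func:`rnadeg.normalization.filter_by_cpm`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample library sizes.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample.
    lib_sizes
        Per-sample library sizes.  If omitted, column sums are used.
    covariates
        Optional per-gene covariates (e.g. dominant-transcript length in
        ``transcript_length``); index must match ``counts``.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series | None = None
    covariates: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, dtype=float)
            if not self.lib_sizes.index.equals(self.counts.columns):
                self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
            if self.lib_sizes.isna().any():
                raise ValueError("lib_sizes missing for some samples")
        if (self.lib_sizes <= 0).any():
            bad = list(self.lib_sizes.index[self.lib_sizes <= 0])
            raise ValueError(f"library sizes must be > 0 (offenders: {bad})")
        if self.covariates is not None and not self.covariates.index.equals(
            self.counts.index
        ):
            self.covariates = self.covariates.reindex(self.counts.index)

    # -- convenience -------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def cpm(self) -> pd.DataFrame:
        """Counts per million: ``counts / lib_size * 1e6`` per sample."""
        return self.counts.div(self.lib_sizes, axis=1) * 1e6

    def subset_genes(self, genes) -> "CountMatrix":
        """Row subset keeping the frozen library sizes."""
        cov = None if self.covariates is None else self.covariates.loc[genes]
        return CountMatrix(self.counts.loc[genes], self.lib_sizes.copy(), cov)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, covariates: pd.DataFrame | None = None
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: count table contains non-integer values")
        return cls(df.round().astype(np.int64), covariates=covariates)
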