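"""Coverage diagnostics and window counting against gene models.

The degradation signature shows up as a decaying histogram of read
3'-distances; this module computes that per-sample profile and turns read
tables into count matrices, counting either every read (full-length
model) or only reads within the 3' window (truncated model).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gene_models import GeneModel
from .matrix import CountMatrix

__all__ = ["coverage_profile", "count_reads_in_window", "cpm"]


def coverage_profile(
    reads: pd.DataFrame, max_bp: int = 3000, bin_bp: int = 50
) -> pd.DataFrame:
    """Per-sample histogram of read 3'-distances, normalized to fractions.

    Returns a DataFrame indexed by bin left edge (bp from the 3' end,
    width ``bin_bp``) with one column per sample; each column sums to 1
    over the bins covering the observed distances (reads beyond
    ``max_bp`` are pooled into the last bin).
    """
    if reads.empty:
        raise ValueError("read table is empty; cannot build a coverage profile")
    if max_bp <= 0 or bin_bp <= 0 or max_bp % bin_bp:
        raise ValueError("max_bp must be a positive multiple of bin_bp")
    edges = np.arange(0, max_bp + bin_bp, bin_bp)
    cols = {}
    for sample, grp in reads.groupby("sample_id", sort=True):
        d = np.minimum(grp["three_prime_distance_bp"].to_numpy(), max_bp - 1e-9)
        hist, _ = np.histogram(d, bins=edges)
        cols[sample] = hist / hist.sum()
    out = pd.DataFrame(cols, index=pd.Index(edges[:-1], name="bin_left_bp"))
    return out


def count_reads_in_window(
    reads: pd.DataFrame,
    models: list[GeneModel] | list[str],
    window_bp: int | None = None,
) -> CountMatrix:
    """Count reads per gene and sample, optionally within the 3' window.

    A read contributes iff its 3'-distance ``d`` satisfies
    ``d < window_bp`` (half-open; a read at exactly the window edge is
    excluded); ``window_bp=None`` counts every read.  All genes in
    ``models`` appear as rows, zero-filled where no reads landed; reads
    naming unknown genes raise with the offending ids listed.
    """
    if window_bp is not None and window_bp < 0:
        raise ValueError("window_bp must be >= 0 or None")
    if models and isinstance(models[0], GeneModel):
        gene_ids = [m.gene_id for m in models]
        lengths = pd.Series(
            {m.gene_id: m.dominant_transcript.spliced_length_bp for m in models}
        )
    else:
        gene_ids = list(models)
        lengths = None
    known = set(gene_ids)
    offenders = sorted(set(reads["gene_id"]) - known)
    if offenders:
        shown = ", ".join(offenders[:10])
        raise ValueError(
            f"{len(offenders)} read gene id(s) absent from models: {shown}"
        )

    kept = reads
    if window_bp is not None:
        kept = reads[reads["three_prime_distance_bp"] < window_bp]
    samples = pd.unique(reads["sample_id"])
    table = (
        kept.groupby(["gene_id", "sample_id"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=gene_ids, columns=samples, fill_value=0)
        .astype(np.int64)
    )
    table.index.name = "gene_id"
    cov = None
    if lengths is not None:
        cov = pd.DataFrame({"transcript_length": lengths.reindex(gene_ids)})
    # Empty-window matrices are legal output but have zero column sums, so
    # set library sizes to 1 to keep the container valid.
    libs = table.sum(axis=0).astype(float)
    if (libs == 0).any():
        libs = libs.replace(0, 1.0)
    return CountMatrix(table, lib_sizes=libs, covariates=cov)


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: ``counts / library_size * 1e6``."""
    return counts.cpm()
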