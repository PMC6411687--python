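"""Expression pre-filtering and covariate-binned TMM normalization.

Plain TMM assumes the count-vs-reference log-ratio is exchangeable across
genes; differential degradation breaks that assumption by tying the
log-ratio to transcript length (and, more weakly, to expression level).
The remedy implemented here splits genes into quantile bins of the
confounding covariate, runs TMM independently inside each bin, and merges
the bins back, so each gene's scaling factor is estimated only from genes
that share its covariate stratum.

The TMM factor itself follows the published recipe: reference sample by
the 75th-percentile rule, per-gene log-ratio M and abundance A against
the reference, double trimming (30% on M, 5% on A), and a
precision-weighted mean of the surviving M values.

Library sizes used for CPM and TMM are the original column totals,
frozen before any filtering, so results do not depend on filter order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import CountMatrix

__all__ = [
    "filter_by_cpm",
    "assign_bins",
    "tmm_factors",
    "binned_normalize",
    "abundance_renormalize",
    "NormalizationResult",
]

logger = logging.getLogger(__name__)


def filter_by_cpm(
    counts: CountMatrix, cpm_threshold: float = 2.0, min_samples: int = 3
) -> CountMatrix:
    """Drop weakly expressed genes: keep g iff CPM > threshold in >= k samples.

    The comparison is strict (CPM exactly at the threshold does not
    count).  Library sizes are *not* recomputed after filtering.
    """
    keep = (counts.cpm() > cpm_threshold).sum(axis=1) >= min_samples
    return counts.subset_genes(counts.genes[keep])


def assign_bins(covariate: pd.Series, n_bins: int = 10) -> pd.Series:
    """Quantile bins of near-equal size, ordered by covariate.

    Genes are sorted by covariate and sliced into ``n_bins`` contiguous
    groups whose sizes differ by at most one.  Tied covariate values are
    kept in one bin (the bin of the tie group's median member), so with
    heavy ties bin sizes may deviate — degenerate covariates collapse to
    a single effective bin.
    """
    n = len(covariate)
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes ({n})")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    order = np.argsort(covariate.to_numpy(), kind="stable")
    raw = np.empty(n, dtype=int)
    raw[order] = np.arange(n) * n_bins // n
    bins = pd.Series(raw, index=covariate.index, name="bin")
    # Reunite tie groups split across a bin boundary.
    for _, idx in covariate.groupby(covariate, sort=False).groups.items():
        if len(idx) > 1:
            vals = bins.loc[idx]
            if vals.nunique() > 1:
                bins.loc[idx] = int(np.median(vals))
    return bins


def _quantile75(counts: pd.DataFrame, lib_sizes: pd.Series) -> pd.Series:
    return counts.quantile(0.75, axis=0) / lib_sizes


def _tmm_one_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float | None:
    """Unscaled log2 TMM factor of one sample against the reference.

    Returns None when no genes survive trimming (caller falls back to 1).
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return None
    y_k, y_r = obs[pos].astype(float), ref[pos].astype(float)
    m = np.log2((y_k / n_obs) / (y_r / n_ref))
    a = 0.5 * np.log2((y_k / n_obs) * (y_r / n_ref))
    w = 1.0 / ((n_obs - y_k) / (n_obs * y_k) + (n_ref - y_r) / (n_ref * y_r))
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() <= 0:
        return None
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference is the sample whose 75th-percentile CPM is closest to
    the mean 75th percentile across samples.  For each sample, genes
    positive in both it and the reference contribute a log-ratio M and
    average abundance A; the upper/lower ``trim_m`` of M and ``trim_a``
    of A are discarded and the factor is the precision-weighted mean of
    the surviving M values.  Factors are rescaled to geometric mean 1.
    A sample with no usable genes after trimming falls back to factor 1
    with a logged warning.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    f75 = _quantile75(counts.counts, counts.lib_sizes)
    ref = (f75 - f75.mean()).abs().idxmin()
    ref_vec = counts.counts[ref].to_numpy()
    n_ref = float(counts.lib_sizes[ref])
    log2f = {}
    for sample in counts.samples:
        if sample == ref:
            log2f[sample] = 0.0
            continue
        val = _tmm_one_pair(
            counts.counts[sample].to_numpy(),
            ref_vec,
            float(counts.lib_sizes[sample]),
            n_ref,
            trim_m,
            trim_a,
        )
        if val is None:
            logger.warning(
                "TMM: no usable genes for sample %s after trimming; factor -> 1",
                sample,
            )
            val = 0.0
        log2f[sample] = val
    f = pd.Series({s: 2.0 ** v for s, v in log2f.items()})[counts.samples]
    return f / np.exp(np.log(f).mean())


@dataclass
class NormalizationResult:
    """Binned TMM output: factors, bin map, and adjusted pseudo-counts.

    ``pseudo`` holds real-valued adjusted counts
    ``y_gs * N_tilde / (N_s * f_{s,b(g)})`` where ``N_tilde`` is the
    geometric mean library size; every sample's effective library size is
    therefore ``N_tilde``.  ``factors`` is bins x samples; within each
    bin the factors have geometric mean 1.
    """

    factors: pd.DataFrame
    bins: pd.Series
    pseudo: pd.DataFrame
    effective_lib_size: float
    covariate: str
    previous: "NormalizationResult | None" = None

    @property
    def gene_factors(self) -> pd.DataFrame:
        """Per-gene, per-sample factor (the gene's bin row)."""
        return self.factors.loc[self.bins.to_numpy()].set_axis(self.bins.index)


def _binned_tmm(
    counts: pd.DataFrame, lib_sizes: pd.Series, covariate: pd.Series, n_bins: int
) -> tuple[pd.DataFrame, pd.Series]:
    bins = assign_bins(covariate, n_bins)
    rows = {}
    for b in sorted(bins.unique()):
        sub = CountMatrix(counts.loc[bins[bins == b].index], lib_sizes=lib_sizes)
        rows[b] = tmm_factors(sub)
    factors = pd.DataFrame(rows).T
    factors.index.name = "bin"
    return factors, bins


def binned_normalize(
    counts: CountMatrix, covariate: str = "transcript_length", n_bins: int = 10
) -> NormalizationResult:
    """Per-bin TMM over a gene covariate, merged back to one matrix.

    ``covariate`` is a column of ``counts.covariates`` (dominant
    transcript length for the degradation correction) or
    ``'average_cpm'`` computed from the matrix itself.  With
    ``n_bins=1`` this reduces exactly to plain TMM normalization.
    """
    cov = _resolve_covariate(counts, covariate)
    factors, bins = _binned_tmm(counts.counts, counts.lib_sizes, cov, n_bins)
    n_tilde = float(np.exp(np.log(counts.lib_sizes).mean()))
    per_gene = factors.loc[bins.to_numpy()].set_axis(counts.genes)
    pseudo = counts.counts / (counts.lib_sizes * per_gene) * n_tilde
    return NormalizationResult(
        factors=factors,
        bins=bins,
        pseudo=pseudo,
        effective_lib_size=n_tilde,
        covariate=covariate,
    )


def _resolve_covariate(counts: CountMatrix, covariate: str) -> pd.Series:
    if covariate == "average_cpm":
        return counts.cpm().mean(axis=1)
    if counts.covariates is None or covariate not in counts.covariates:
        raise ValueError(f"covariate {covariate!r} not available on the count matrix")
    return counts.covariates[covariate]


def abundance_renormalize(
    result: NormalizationResult, n_bins: int = 10
) -> NormalizationResult:
    """Second binned-TMM pass with average CPM as the covariate.

    Applied to the pseudo-counts of a previous pass, it removes residual
    fold-change dependence on expression level; on unbiased input it is
    close to the identity.  The returned result composes both passes
    (its ``pseudo`` is the final matrix; ``previous`` links the first
    pass).
    """
    libs = pd.Series(result.effective_lib_size, index=result.pseudo.columns)
    avg_cpm = (result.pseudo / result.effective_lib_size * 1e6).mean(axis=1)
    factors, bins = _binned_tmm(result.pseudo, libs, avg_cpm, n_bins)
    per_gene = factors.loc[bins.to_numpy()].set_axis(result.pseudo.index)
    pseudo = result.pseudo / per_gene
    return NormalizationResult(
        factors=factors,
        bins=bins,
        pseudo=pseudo,
        effective_lib_size=result.effective_lib_size,
        covariate="average_cpm",
        previous=result,
    )
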