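"""Synthetic RNA-seq data with controlled 3'-degradation bias.

Emulates the failure mode that motivates 3'-truncated counting: when RNA
integrity (RIN) differs between samples, reads pile up near the 3' end of
transcripts in the degraded samples, so full-length counting inflates
short transcripts and deflates long ones, confounding length with fold
change.

The degradation model is an exponential survival of spliced positions
from the 3' end: a read's 3'-distance ``d`` on a transcript of spliced
length ``L`` has density proportional to ``exp(-d / lambda_s)`` truncated
at ``L``, where ``lambda_s`` (bp) is the per-sample decay scale playing
the role of RIN (larger = more intact; ``inf`` = uniform coverage).  The
expected read yield of a gene is then ``mu_gs * (1 - exp(-L/lambda_s))``
for full-length counting and ``mu_gs * (1 - exp(-min(L, w)/lambda_s))``
when counting only the window of ``w`` bp next to the 3' end.

Counts can be generated gene-level from the closed-form window integral
(fast path) or read-by-read (for coverage QC); both share the same
expected values.  Biological noise is negative binomial with variance
``mu + phi * mu**2``.

Default scale mirrors the emulated study design — 2 genotypes x 2 sexes x
3 ages x 3 biological replicates — at desk scale: 2000 genes and 2e5
reads per sample instead of genome-wide and >=20e6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_models import Exon, GeneModel, Transcript
from .matrix import CountMatrix

__all__ = [
    "SampleSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_design",
    "two_group_design",
    "simulate_gene_models",
    "simulate_read_positions",
    "simulate_counts",
    "expression_means",
    "window_retention",
    "target_library_sizes",
    "simulate_gene_sets",
    "simulate_ct_table",
    "write_design",
    "write_reads",
    "read_reads",
]

GENOTYPES = ("Tg", "NTg")
SEXES = ("M", "F")
AGES = ("young", "mature", "old")

# Stage offsets keep each stochastic stage on an independent, reproducible
# stream derived from the one user-facing seed.
_STAGE = {"models": 1, "libsizes": 2, "counts": 3, "reads": 4, "sets": 5, "ct": 6}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], seed])


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing library: design factors plus its degradation scale."""

    sample_id: str
    genotype: str
    sex: str
    age: str
    replicate: int
    decay_scale_bp: float  # lambda_s; math.inf = no degradation (uniform)

    def __post_init__(self) -> None:
        if not self.decay_scale_bp > 0:
            raise ValueError(
                f"sample {self.sample_id}: decay_scale_bp must be > 0, "
                f"got {self.decay_scale_bp}"
            )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``de_factor``/``de_group`` name the design column and level whose
    samples receive the spiked ``de_log2fc`` on the DE genes.
    """

    design: list[SampleSpec]
    n_genes: int = 2000
    length_range_bp: tuple[int, int] = (500, 10_000)
    n_transcripts_per_gene_range: tuple[int, int] = (1, 3)
    baseline_mean_range: tuple[float, float] = (10.0, 1000.0)
    dispersion: float = 0.1
    de_fraction: float = 0.0
    de_log2fc: float = 2.0
    de_factor: str = "genotype"
    de_group: str = "Tg"
    reads_per_sample: int = 200_000
    window_bp: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in ("length_range_bp", "n_transcripts_per_gene_range", "baseline_mean_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not self.design:
            raise ValueError("design must contain at least one sample")
        ids = [s.sample_id for s in self.design]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")
        if self.de_fraction > 0:
            in_group = sum(
                getattr(s, self.de_factor) == self.de_group for s in self.design
            )
            if in_group < 2 or len(self.design) - in_group < 2:
                raise ValueError(
                    "DE simulation needs >=2 samples on each side of "
                    f"{self.de_factor}={self.de_group}"
                )

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class GroundTruth:
    """What the simulator actually planted, for recovery tests.

    ``genes``: per-gene table (dominant transcript, spliced length,
    baseline mean, DE flag, true log2FC); ``samples``: per-sample decay
    scale and design factors.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame

    def to_tsv(self, gene_path: str | Path, sample_path: str | Path) -> None:
        g = self.genes.copy()
        g.index.name = "gene_id"
        g.to_csv(gene_path, sep="\t", float_format="%.6g")
        s = self.samples.copy()
        s.index.name = "sample_id"
        s.to_csv(sample_path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

def default_design(
    seed: int = 0, decay_range_bp: tuple[float, float] = (800.0, 4000.0)
) -> list[SampleSpec]:
    """The emulated study layout: 2 genotypes x 2 sexes x 3 ages x 3 reps.

    Decay scales are drawn log-uniformly per library within
    ``decay_range_bp`` — degradation varied between the study's libraries
    without tracking any design factor.
    """
    rng = np.random.default_rng([7, seed])
    design = []
    for genotype in GENOTYPES:
        for sex in SEXES:
            for age in AGES:
                for rep in range(1, 4):
                    lam = float(
                        np.exp(rng.uniform(np.log(decay_range_bp[0]), np.log(decay_range_bp[1])))
                    )
                    design.append(
                        SampleSpec(
                            f"{genotype}_{sex}_{age}_r{rep}",
                            genotype,
                            sex,
                            age,
                            rep,
                            lam,
                        )
                    )
    return design


def two_group_design(
    n_per_group: int = 3,
    decay_a: float = 4000.0,
    decay_b: float = 800.0,
    de_group_is_a: bool = True,
) -> list[SampleSpec]:
    """Minimal 2-group layout (genotype contrast) with fixed decay scales.

    Group A = Tg with ``decay_a``; group B = NTg with ``decay_b``.  With
    unequal decay scales and no DE this is the degradation-confounded
    null that full-length counting mistakes for expression change.
    """
    design = []
    for rep in range(1, n_per_group + 1):
        design.append(SampleSpec(f"Tg_M_young_r{rep}", "Tg", "M", "young", rep, decay_a))
    for rep in range(1, n_per_group + 1):
        design.append(SampleSpec(f"NTg_M_young_r{rep}", "NTg", "M", "young", rep, decay_b))
    return design


def design_frame(design: list[SampleSpec]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "genotype": [s.genotype for s in design],
            "sex": [s.sex for s in design],
            "age": [s.age for s in design],
            "replicate": [s.replicate for s in design],
            "decay_scale_bp": [s.decay_scale_bp for s in design],
        },
        index=pd.Index([s.sample_id for s in design], name="sample_id"),
    )
    return df


def write_design(design: list[SampleSpec], path: str | Path) -> None:
    design_frame(design).to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _log_uniform_int(rng, lo: float, hi: float, size: int) -> np.ndarray:
    return np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), size))).astype(int)


def _build_transcript(
    rng, tid: str, chrom: str, gene_start: int, strand: str, spliced_len: int, abundance: float
) -> tuple[Transcript, int]:
    """Random 1-4 exon chain with the requested spliced length."""
    max_exons = min(4, spliced_len)
    n_exons = int(rng.integers(1, max_exons + 1))
    if n_exons == 1:
        pieces = [spliced_len]
    else:
        cuts = np.sort(rng.choice(np.arange(1, spliced_len), size=n_exons - 1, replace=False))
        bounds = np.concatenate(([0], cuts, [spliced_len]))
        pieces = np.diff(bounds).tolist()
    introns = rng.integers(50, 501, size=n_exons - 1).tolist()
    pos = gene_start + int(rng.integers(0, 50))
    exons = []
    for i, width in enumerate(pieces):
        exons.append(Exon(chrom, pos, pos + int(width), strand))
        pos += int(width)
        if i < n_exons - 1:
            pos += int(introns[i])
    return Transcript(tid, exons, abundance=abundance), pos


def simulate_gene_models(config: SimulationConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Generate gene models and the planted truth.

    Each gene carries 1..k isoforms with distinct abundances (one strict
    maximum, the dominant isoform used downstream as the counting model);
    spliced lengths are log-uniform within ``length_range_bp``; genes are
    laid out non-overlapping on one chromosome.
    """
    rng = _rng(config.seed, "models")
    n = config.n_genes
    width = max(4, len(str(n)))
    lo_l, hi_l = config.length_range_bp
    lengths = _log_uniform_int(rng, lo_l, hi_l, n)
    lengths = np.clip(lengths, lo_l, hi_l)
    baseline = np.exp(
        rng.uniform(np.log(config.baseline_mean_range[0]), np.log(config.baseline_mean_range[1]), n)
    )
    de_flags = np.zeros(n, dtype=bool)
    if config.n_de:
        de_flags[rng.choice(n, size=config.n_de, replace=False)] = True
    true_lfc = np.where(de_flags, config.de_log2fc, 0.0)

    models: list[GeneModel] = []
    dominants: list[str] = []
    cursor = 1000
    lo_t, hi_t = config.n_transcripts_per_gene_range
    for i in range(n):
        gid = f"g{i:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(lo_t, hi_t + 1))
        # Distinct abundances with a strict maximum for the dominant isoform.
        abund = np.sort(rng.uniform(0.05, 1.0, size=n_tx))[::-1]
        abund[0] *= 1.5
        tx_lengths = [int(lengths[i])] + _log_uniform_int(rng, lo_l, hi_l, n_tx - 1).tolist()
        transcripts = []
        gene_end = cursor
        for j in range(n_tx):
            tid = f"{gid}.t{j + 1}"
            tx, end = _build_transcript(
                rng, tid, "chrS", cursor, strand, tx_lengths[j], float(abund[j])
            )
            transcripts.append(tx)
            gene_end = max(gene_end, end)
        models.append(GeneModel(gid, transcripts, dominant=transcripts[0].id))
        dominants.append(transcripts[0].id)
        cursor = gene_end + 1000

    genes = pd.DataFrame(
        {
            "dominant_transcript": dominants,
            "length_bp": lengths,
            "baseline_mean": baseline,
            "is_de": de_flags,
            "true_log2fc": true_lfc,
        },
        index=pd.Index([m.gene_id for m in models], name="gene_id"),
    )
    truth = GroundTruth(genes=genes, samples=design_frame(config.design))
    return models, truth


# ---------------------------------------------------------------------------
# Expression and counts
# ---------------------------------------------------------------------------

def expression_means(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Per-gene, per-sample true transcript abundance mu_gs (full length).

    DE genes are shifted by ``de_log2fc`` in the samples whose
    ``de_factor`` equals ``de_group``; all other genes are identical
    across groups (null).
    """
    base = truth.genes["baseline_mean"].to_numpy()[:, None]
    lfc = truth.genes["true_log2fc"].to_numpy()[:, None]
    in_group = np.array(
        [truth.samples.loc[s.sample_id, config.de_factor] == config.de_group for s in config.design]
    )[None, :]
    mu = base * np.where(in_group, 2.0 ** lfc, 1.0)
    return pd.DataFrame(
        mu, index=truth.genes.index, columns=[s.sample_id for s in config.design]
    )


def window_retention(length_bp, decay_scale_bp: float, window_bp: float | None) -> np.ndarray:
    """Integral of the decay density over the counting window.

    Returns ``1 - exp(-min(L, w)/lambda)`` (unnormalized mass within the
    window); for ``lambda = inf`` the uniform limit ``min(L, w) / L``
    relative to full length is used, scaled so that full-length retention
    is 1 in both parameterizations' common limit.
    """
    L = np.asarray(length_bp, dtype=float)
    w = L if window_bp is None else np.minimum(L, float(window_bp))
    if math.isinf(decay_scale_bp):
        return w / L
    return -np.expm1(-w / decay_scale_bp)


def target_library_sizes(config: SimulationConfig) -> pd.Series:
    """Per-sample target depths, uniform +/-20% around reads_per_sample."""
    rng = _rng(config.seed, "libsizes")
    factors = rng.uniform(0.8, 1.2, size=len(config.design))
    return pd.Series(
        np.rint(config.reads_per_sample * factors).astype(int),
        index=[s.sample_id for s in config.design],
    )


def expected_counts(
    truth: GroundTruth, config: SimulationConfig, mode: str = "full_length"
) -> pd.DataFrame:
    """Expected reads per gene/sample under the chosen counting mode.

    Full-length expectations are allocated so each sample's total equals
    its target depth (multinomial allocation); truncated expectations are
    the full-length ones thinned by the within-window fraction of each
    gene's reads, mirroring read-level window counting.
    """
    if mode not in ("full_length", "truncated_500"):
        raise ValueError(f"unknown mode {mode!r}")
    mu = expression_means(truth, config)
    L = truth.genes["length_bp"]
    libs = target_library_sizes(config)
    cols = {}
    for spec in config.design:
        lam = spec.decay_scale_bp
        w_full = mu[spec.sample_id].to_numpy() * window_retention(L, lam, None)
        mean_full = libs[spec.sample_id] * w_full / w_full.sum()
        if mode == "truncated_500":
            keep = window_retention(L, lam, config.window_bp) / window_retention(L, lam, None)
            mean_full = mean_full * keep
        cols[spec.sample_id] = mean_full
    return pd.DataFrame(cols, index=truth.genes.index)


def _nb_draw(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    truth: GroundTruth, config: SimulationConfig, mode: str = "full_length"
) -> CountMatrix:
    """Gene-level NB counts from the closed-form window integral.

    ``mode='full_length'`` integrates the decay density over [0, L];
    ``'truncated_500'`` over [0, min(L, window)].  Per-gene counts are
    NB(mean, dispersion) draws around the expected allocation.
    """
    rng = _rng(config.seed, "counts")
    means = expected_counts(truth, config, mode)
    counts = pd.DataFrame(
        {s: _nb_draw(rng, means[s].to_numpy(), config.dispersion) for s in means.columns},
        index=means.index,
    ).astype(np.int64)
    cov = pd.DataFrame({"transcript_length": truth.genes["length_bp"]})
    return CountMatrix(counts, covariates=cov)


def simulate_read_positions(
    models: list[GeneModel], truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Read-level simulation: NB read yield per gene, then 3'-distances.

    Distances are drawn from the truncated exponential by inverse CDF on
    the dominant transcript (``d = -lambda*log(1 - u*(1-exp(-L/lambda)))``),
    or uniformly on [0, L) when ``lambda = inf``.  Full-length window
    counting of the returned table reproduces ``simulate_counts`` in
    expectation.
    """
    rng = _rng(config.seed, "reads")
    means = expected_counts(truth, config, "full_length")
    L = truth.genes["length_bp"].to_numpy().astype(float)
    gene_ids = truth.genes.index.to_numpy()
    tx_ids = truth.genes["dominant_transcript"].to_numpy()
    frames = []
    for spec in config.design:
        n_reads = _nb_draw(rng, means[spec.sample_id].to_numpy(), config.dispersion)
        total = int(n_reads.sum())
        gene_rep = np.repeat(np.arange(len(gene_ids)), n_reads)
        Lr = L[gene_rep]
        u = rng.random(total)
        lam = spec.decay_scale_bp
        if math.isinf(lam):
            d = u * Lr
        else:
            d = -lam * np.log1p(-u * -np.expm1(-Lr / lam))
        # round to the TSV precision so on-disk and in-memory tables agree,
        # keeping d strictly below the spliced length
        d = np.minimum(np.round(d, 3), Lr - 1e-3)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": spec.sample_id,
                    "gene_id": gene_ids[gene_rep],
                    "transcript_id": tx_ids[gene_rep],
                    "three_prime_distance_bp": d,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_reads(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Companion synthetic inputs: gene sets and qPCR plates
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    truth: GroundTruth,
    config: SimulationConfig,
    n_sets: int = 20,
    size_range: tuple[int, int] = (15, 60),
    n_enriched: int = 4,
    enriched_de_fraction: float = 0.6,
) -> dict[str, list[str]]:
    """Named gene sets over the simulated genes, some enriched in DE genes.

    The first ``n_enriched`` sets draw ``enriched_de_fraction`` of their
    members from the planted DE genes (when any exist); the rest are
    uniform draws, serving as null sets.
    """
    rng = _rng(config.seed, "sets")
    genes = truth.genes.index.to_numpy()
    de_genes = truth.genes.index[truth.genes["is_de"]].to_numpy()
    out: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if i < n_enriched and len(de_genes) > 0:
            k_de = min(len(de_genes), int(round(size * enriched_de_fraction)))
            members = list(rng.choice(de_genes, size=k_de, replace=False))
            rest = rng.choice(genes, size=size - k_de, replace=False)
            members = sorted(set(members) | set(rest))
            name = f"SET_DE_{i:02d}"
        else:
            members = sorted(rng.choice(genes, size=size, replace=False))
            name = f"SET_NULL_{i:02d}"
        out[name] = members
    return out


def simulate_ct_table(
    seed: int = 0,
    target_genes: tuple[str, ...] = ("Mlp60A", "Act88F", "Arc1"),
    reference_genes: tuple[str, ...] = ("act5c", "tub84B"),
    true_log2fc: tuple[float, ...] = (-1.0, -0.8, 1.2),
    n_per_group: int = 6,
    n_technical: int = 3,
    ct_sd: float = 0.12,
) -> pd.DataFrame:
    """Synthetic qPCR plate in long format (one row per technical well).

    Treated samples shift the target gene's Ct by ``-true_log2fc`` cycles
    relative to control (a 2-fold expression change is one cycle);
    reference genes are flat across groups up to noise.
    """
    rng = _rng(seed, "ct")
    rows = []
    base_ct = {g: float(rng.uniform(18, 26)) for g in reference_genes + target_genes}
    lfc = dict(zip(target_genes, true_log2fc))
    for group in ("control", "treated"):
        for i in range(1, n_per_group + 1):
            sample = f"{group[:4]}_{i}"
            sample_shift = float(rng.normal(0, 0.3))  # loading/RT variation
            for gene in reference_genes + target_genes:
                ct = base_ct[gene] + sample_shift
                if group == "treated" and gene in lfc:
                    ct -= lfc[gene]
                for _ in range(n_technical):
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "ct": round(float(ct + rng.normal(0, ct_sd)), 3),
                        }
                    )
    return pd.DataFrame(rows)
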