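# Methods

## The problem

Bulk RNA-seq libraries primed from the poly(A) tail lose coverage with
distance from the 3′ end when the input RNA is degraded. If RNA integrity
(RIN) differs *between* samples — as it routinely does across ages,
tissues and extraction batches — the loss is sample-specific, and the
apparent fold change of a gene between two samples becomes a function of
its transcript length: short transcripts look spuriously up-regulated in
the degraded samples, long transcripts spuriously down. Any
differential-expression (DE) analysis that counts reads over full-length
gene models then reports length, not biology.

`rnadeg` implements the counter-measures as one tested pipeline:

1. **3′-truncated gene models** — per gene, keep the single most abundant
   isoform and truncate it to the last 500 bp of spliced sequence before
   the 3′ end, the region degradation leaves comparatively intact; count
   reads against this reduced model.
2. **Covariate-binned TMM normalization** — pre-filter weakly expressed
   genes (CPM > 2 in ≥ 3 samples), split the survivors into 10
   transcript-length quantile bins, compute TMM scaling factors
   independently within each bin, and merge the adjusted pseudo-counts.
   An optional second pass repeats the procedure with average CPM as the
   covariate.
3. **NB exact test** on the rounded pseudo-counts with a common
   conditional-ML dispersion, BH FDR, threshold filters and Venn
   intersections of DE lists.
4. **Top-list Fisher enrichment** — hypergeometric upper-tail tests of
   the top 50/100/200/500/1000 up- and down-regulated genes against the
   pre-filtered background, merged per gene set and direction as the
   minimum p across list sizes.
5. **qPCR 2^−ΔΔCt quantification** with two reference genes and exact
   nonparametric group comparison, the validation arm of the workflow.

## Degradation model (simulator)

The synthetic-data module generates every input with known ground truth.
Degradation is modelled as exponential survival from the 3′ end: a read's
3′-distance `d` on a transcript of spliced length `L` in sample `s` has
density ∝ `exp(−d/λ_s)` truncated at `L`. The decay scale `λ_s` (bp)
plays the role of RIN: large `λ` (or ∞, the uniform limit) means intact
RNA; small `λ` concentrates reads at the 3′ end. The expected read yield
of a gene with abundance `μ_gs` is

* full-length counting: `μ_gs · (1 − e^{−L/λ_s})`
* `w` bp 3′-window counting: `μ_gs · (1 − e^{−min(L,w)/λ_s})`,

so for all `L ≥ w` the window yield is length-independent — the whole
point of truncated counting. Counts are generated either gene-level from
these closed-form integrals (fast path) or read-by-read (for coverage
QC); the two agree in expectation, which is tested.

Per sample, expected full-length yields are normalized to a target depth
(multinomial allocation), and biological noise is negative binomial with
variance `μ + φμ²`. Read-level 3′-distances come from the inverse CDF of
the truncated exponential and are emitted at the 0.001 bp precision of
the TSV format, so in-memory and on-disk tables agree exactly.

### Study conditions and scale

The default design mirrors the emulated experiment: 2 genotypes (Tg =
transgenic, NTg = control) × 2 sexes × 3 ages × 3 biological replicates
= 36 libraries, analysed per-stratum. Scale is reduced to desk size:
2000 genes (spliced lengths log-uniform in 500–10 000 bp, 1–3 isoforms
each, 1–4 exons, one strict abundance maximum) and 2×10⁵ reads per
library instead of genome-wide annotation and ≥ 2×10⁷ reads. Library
depths are jittered ±20 % around the target to exercise normalization.
Baseline expression is log-uniform in 10–1000 expected counts;
dispersion defaults to φ = 0.1, a typical bulk-RNA-seq replicate value.
No quantitative λ-per-RIN mapping exists, so decay scales are a repo
choice: log-uniform per library in 800–4000 bp, and the fixed
contrast λ = 4000 vs 800 bp for the confounded-null benchmark, chosen so
that full-length coverage beyond ~750–1000 bp collapses in the degraded
group while the 0–500 bp window is largely preserved. Spiked DE uses a
single planted `log2FC` (default 2) applied to the Tg samples of a
configurable fraction of genes (default 5 %).

What the simulator does **not** emulate: sequencing error, positional
fragment-length effects, GC bias, isoform switching between conditions,
overlapping genes, and correlated gene-gene variation. Passing tests
therefore demonstrate correctness of the pipeline's arithmetic and its
behaviour under the degradation model — not robustness to every artefact
of real libraries.

## Gene models and truncation

Internal coordinates are 0-based half-open; GTF I/O converts to the
on-disk 1-based inclusive convention at the boundary. The dominant
isoform is the argmax of abundance (global across samples, keeping a
single counting model per gene); ties break by longer spliced length,
then lexicographically smallest transcript id — deterministic and
documented, since the choice is otherwise arbitrary. Truncation walks
exons from the 3′ end (highest genomic coordinate on `+`, lowest on `−`)
until 500 spliced bases are kept; a shorter transcript is returned
unchanged, making the operation idempotent. Window membership for read
counting is half-open, `d < w`: a read at exactly 500 bp is excluded,
consistent with the coordinate convention.

## Normalization

TMM follows the published recipe with its canonical defaults, which the
method's name implies but which are stated here because they matter:

* reference sample: the one whose 75th-percentile CPM is closest to the
  mean 75th percentile;
* per gene positive in both sample `k` and reference `r`:
  `M_g = log2[(y_gk/N_k)/(y_gr/N_r)]`, `A_g = ½·log2[(y_gk/N_k)(y_gr/N_r)]`;
* double trim: drop the upper/lower 30 % of `M` and 5 % of `A`
  (rank-based, average ties);
* `log2 f_k = Σ w_g M_g / Σ w_g` with precision weights
  `w_g = [(N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr)]^{−1}`;
* factors rescaled to geometric mean 1; a sample with no usable genes
  after trimming falls back to factor 1 with a logged warning.

The implementation is cross-checked against an unvectorized scalar
oracle (to 1e−10) and against edgeR's `calcNormFactors` via Rscript
(to 1e−6).

Binning uses equal-count quantile bins of the covariate (sizes differ by
at most 1; tied covariate values stay together, so degenerate covariates
collapse to one bin). Equal-count bins were chosen because per-bin TMM
needs comparable gene numbers to be stable. Pseudo-counts are
`ŷ_gs = y_gs · Ñ/(N_s·f_{s,b(g)})` with `Ñ` the geometric mean library
size, so every sample sits on the common effective depth `Ñ`. Library
sizes for CPM, filtering and TMM are the original column totals, frozen
before filtering, which removes any dependence on filter order. The
length-bin pass runs first; the CPM-bin pass (`abundance_renormalize`)
is implemented and tested but off by default — with length-binned input
it is near the identity, and keeping it optional makes the headline
pipeline a single, auditable correction.

Pseudo-counts stay real-valued in the normalization result; rounding
(half-to-even) happens only where the exact test needs integers.

## Differential expression

After normalization the libraries share the effective size `Ñ`, so
within a group the replicate counts of a null gene are i.i.d. NB(μ, φ)
and the group sum over `n` replicates is NB with mean `nμ` and
dispersion `φ/n`.

**Common dispersion** maximizes the conditional log-likelihood summed
over genes and groups; for one gene with replicate counts `y_j` summing
to `z` in a group of size `n` (writing `r = 1/φ`):

```
ℓ(φ) = Σ_j log Γ(y_j + r) + log Γ(n r) − log Γ(z + n r) − n log Γ(r)
```

maximized by golden-section search on `log φ ∈ [log 1e−4, log 5]`.
All-zero genes contribute exactly zero. The estimate matches edgeR's
`estimateCommonDisp` to ~1e−3 relative and recovers planted φ within the
tested bands.

**Exact test**: condition on the two-group total `s = a + b`; the
two-sided p-value sums the conditional probabilities of every split
whose joint probability is ≤ the observed one (ties kept via a 1+1e−7
relative tolerance, the convention of exact two-sided tests on discrete
data). At φ = 0 the group sums are Poisson and the conditional law is
binomial(s, n₁/(n₁+n₂)); the implementation reaches this limit through
the same code path and is verified against an exact rational-arithmetic
binomial enumeration. For totals above 5000 the split enumeration
switches to a continuity-corrected normal approximation of the
conditional distribution (conditional variance `v₁v₂/(v₁+v₂)` from the
two group-sum variances); the switchover is tested against forced full
enumeration just above the cap and agrees to < 0.02 absolute in p.
`s = 0` returns p = 1 by convention.

log2FC is computed from the *unrounded* group means of pseudo-counts
with a prior count of 0.5 (group 2 over group 1); logCPM is the log2
average CPM at the effective library size. FDR is Benjamini–Hochberg
step-up. Threshold filters annotate direction; Venn logic enumerates all
regions of up to k named DE sets.

Tagwise or trended dispersion and quasi-likelihood F-tests are out of
scope; the common-dispersion exact test is the implemented inference.

## Enrichment

One-sided over-representation only: `p = P(X ≥ k)` for hypergeometric X
with universe N (the pre-filtered gene list — using the filtered
background rather than the genome is deliberate and matters), set size
K, list size n, overlap k. Candidate lists per direction are the genes
with p < 0.05 and the matching fold-change sign, ranked by p (ties: 
|log2FC| descending, then gene id), sliced at the top
50/100/200/500/1000. The merged statistic per (set, direction) is the
minimum p across list sizes. This merge is **not** corrected for trying
five sizes and is anti-conservative by construction — a property test
demonstrates the inflation on permuted rankings — so a
Bonferroni-across-5-lists companion column is always reported next to
it.

## qPCR

Technical replicates are averaged first; `ΔCt = Ct_target − mean(Ct_refs)`
(arithmetic mean over the two reference genes, equivalent to normalizing
expression by their geometric mean); `ΔΔCt` subtracts the control-group
mean ΔCt, making the control geometric-mean ratio exactly 1; expression
ratio = `2^−ΔΔCt`, summarized over treated samples by geometric mean.
Group comparisons use the exact Mann-Whitney U (unpaired) or Wilcoxon
signed-rank (paired) for group sizes ≤ 12 without ties, the
tie-corrected normal approximation otherwise. Efficiency correction
(Pfaffl) and standard curves are out of scope.

## Numerical and design choices

* Half-to-even rounding for pseudo-count integerization (unbiased).
* Enumeration arrays use log-space pmfs with `logsumexp`; no underflow
  up to the 5000 cap.
* Deterministic runs: every stochastic stage draws from
  `default_rng([stage_offset, seed])`, so stages are independent and a
  stage rerun from the same config reproduces its outputs; TSV floats are
  formatted (`%.6g`, distances `%.3f`) and the manifest stores sha256
  checksums, making whole runs byte-reproducible.
* The pipeline aborts on the first failing stage, naming it; completed
  stages' outputs are retained.

## Problem sizes used by the verification suite

Simulation-based checks run at 1000–2000 genes with 3+3 libraries of
1–3×10⁵ reads: large enough that the measured quantities (Spearman ρ of
log2FC against length, type-I error at p < 0.05, dispersion and log2FC
recovery) have sampling noise well inside the asserted bands, and small
enough to re-run freely. The binomial-equivalence sweep covers every
two-group total up to 200 (all splits up to 60, spot splits beyond); the
hypergeometric comparison covers a margin grid up to N = 200.

## Known limitations

* The exponential-survival decay model is a single-parameter idealization;
  real degradation profiles also depend on fragmentation chemistry and
  priming strategy.
* The common dispersion understates gene-specific variability; with few
  replicates this is the classical bias-variance trade-off, but genes
  with unusually high dispersion will be anticonservative.
* Min-p merging across top-list sizes is reported as such, uncorrected,
  with the conservative companion; it should be read as a screening
  statistic, not a calibrated p-value.
* The second (CPM-bin) normalization pass can chase noise on sparse
  matrices; it is off by default.
* BAM/FASTQ input is out of scope; reads enter as 3′-distance tables
  produced by the simulator (or by an external preprocessor adopting the
  same format).
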