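# rnadeg — degradation-aware RNA-seq differential expression

When RNA integrity differs between sequencing libraries, read coverage
collapses with distance from the transcript 3′ end in the degraded
samples. Counting reads over full-length gene models then confounds
transcript length with expression change: short transcripts appear
up-regulated in low-integrity samples, long ones down-regulated, and a
standard differential-expression analysis reports this artefact as
biology.

`rnadeg` is a tested implementation of the counter-measures, wired into
one pipeline and exercised end-to-end on synthetic data with known
ground truth:

* **3′-truncated gene models** — keep each gene's most abundant isoform
  and truncate it, strand-aware, to the 500 bp of spliced sequence next
  to the 3′ end; count reads in that window (`gene_models`, `coverage`).
* **Length-binned TMM** — pre-filter (CPM > 2 in ≥ 3 samples), split
  genes into 10 transcript-length quantile bins, normalize each bin
  independently by the trimmed mean of M-values, merge into adjusted
  pseudo-counts `ŷ_gs = y_gs·Ñ/(N_s f_{s,b(g)})`; optional second pass
  binned on average CPM (`normalization`).
* **NB exact test** — common dispersion φ by conditional maximum
  likelihood (variance μ + φμ²), two-sided conditional exact test on
  group sums, BH FDR, threshold filters and Venn intersections (`de`).
* **Top-list Fisher enrichment** — hypergeometric upper-tail tests of
  the top 50/100/200/500/1000 up-/down-regulated genes against the
  pre-filtered background, merged per set and direction as the minimum p
  across list sizes (reported with a Bonferroni companion)
  (`enrichment`).
* **qPCR 2^−ΔΔCt** with two reference genes and exact Mann-Whitney /
  Wilcoxon comparisons (`qpcr`).
* **Synthetic data** — exponential 3′-coverage decay `exp(−d/λ_s)` with
  per-library decay scale λ (the RIN surrogate), NB noise, spiked DE,
  multi-isoform genes, GTF/TSV/GMT emission (`simulate`).

The scientific core is the observation that the expected read yield of a
gene of length L in sample s is `μ_gs(1 − e^{−L/λ_s})` under full-length
counting but `μ_gs(1 − e^{−min(L,w)/λ_s})` under w bp 3′-window
counting — length-independent for all L ≥ w — so truncation plus
within-length-bin renormalization removes the degradation bias by
construction. `docs/methods.md` has the full model description and every
default with its rationale.

## Worked example

The numbered drivers under `analysis/` run the whole study on one
simulated dataset (1000 genes, the 2 genotypes × 2 sexes × 3 ages × 3
replicates design, 5 % of genes spiked 4-fold in the transgenic group)
and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_coverage_qc.py
...
python analysis/07_compare_modes.py
```

Output of the key steps (what the scripts actually print):

```
fraction of reads within 500 bp of the 3' end: 0.53 (most degraded,
  lambda=818 bp) vs 0.25 (least degraded, lambda=3754 bp)
Tg_vs_NTg: phi = 0.105, 108 genes at p < 0.05, 10 pass |log2FC| >= 2.0 & p < 0.05
Tg_vs_NTg: strongest merged enrichments ->
  SET_DE_03 (up): min p = 1.29e-34 at top-50 (Bonferroni-5 companion 6.47e-34)
Mlp60A: treated/control = 0.49 (log2 -1.02, planted -1.0), Mann-Whitney p = 0.00216
full-length counting:   |rho(log2FC, length)| = 0.779, false-positive rate at p<0.05 = 0.254
truncated + binned TMM: |rho(log2FC, length)| = 0.025, false-positive rate at p<0.05 = 0.052
```

Reading the last two lines: on a *null* dataset whose two groups differ
only in RNA integrity (λ = 4000 vs 800 bp), full-length counting shows a
strong correlation between fold change and transcript length and a 25 %
false-positive rate at p < 0.05; after 500 bp truncation and
length-binned TMM the correlation is gone and the error rate returns to
the nominal 5 %. The genotype contrast recovers the planted DE genes
(108 at p < 0.05 ≈ 50 spiked + 5 % null rate), the gene sets seeded with
DE genes dominate the enrichment ranking, and the ΔΔCt arm reproduces
the planted fold changes.

The same workflow is scriptable via the `rnadeg` CLI
(`simulate`, `truncate-gtf`, `count`, `normalize`, `de`, `enrich`,
`qpcr`, `run`, `compare-modes`); `rnadeg run --outdir RUN` executes every
stage into a run directory with a checksummed `manifest.json`, and
identical config + seed reproduce it byte for byte.

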