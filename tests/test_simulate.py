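"""Simulator correctness: decay model, count laws, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import spearmanr

from rnadeg.coverage import count_reads_in_window
from rnadeg.gene_models import write_gtf
from rnadeg.simulate import (
    SampleSpec,
    SimulationConfig,
    expected_counts,
    expression_means,
    simulate_counts,
    simulate_gene_models,
    simulate_gene_sets,
    simulate_read_positions,
    target_library_sizes,
    two_group_design,
    window_retention,
)


def _one_gene_config(length, lam, reads=40_000, seed=0, phi=0.0):
    design = [
        SampleSpec("s1", "Tg", "M", "young", 1, lam),
        SampleSpec("s2", "NTg", "M", "young", 1, lam),
    ]
    return SimulationConfig(
        design=design,
        n_genes=1,
        length_range_bp=(length, length),
        n_transcripts_per_gene_range=(1, 1),
        dispersion=phi,
        reads_per_sample=reads,
        seed=seed,
    )


class TestGeneModels:
    def test_single_isoform_gene_dominant_is_only_transcript(self):
        cfg = SimulationConfig(
            design=two_group_design(), n_genes=30,
            n_transcripts_per_gene_range=(1, 1), seed=3,
        )
        models, truth = simulate_gene_models(cfg)
        for m in models:
            assert len(m.transcripts) == 1
            assert m.dominant == m.transcripts[0].id

    def test_fixed_seed_gives_byte_identical_gtf(self, tmp_path):
        paths = []
        for tag in ("a", "b"):
            cfg = SimulationConfig(design=two_group_design(), n_genes=50, seed=7)
            models, _ = simulate_gene_models(cfg)
            p = tmp_path / f"{tag}.gtf"
            write_gtf(models, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_length_distribution_spans_configured_range(self):
        cfg = SimulationConfig(
            design=two_group_design(), n_genes=2000,
            length_range_bp=(500, 10_000), seed=5,
        )
        models, truth = simulate_gene_models(cfg)
        # scan every generated model directly
        lengths = np.array(
            [m.dominant_transcript.spliced_length_bp for m in models]
        )
        assert (lengths >= 500).all() and (lengths <= 10_000).all()
        assert lengths.min() < 700 and lengths.max() > 8000
        assert np.array_equal(lengths, truth.genes["length_bp"].to_numpy())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="length_range_bp"):
            SimulationConfig(design=two_group_design(), length_range_bp=(0, 100))
        with pytest.raises(ValueError, match="decay_scale_bp"):
            SampleSpec("s", "Tg", "M", "young", 1, -5.0)
        with pytest.raises(ValueError, match=">=2 samples"):
            SimulationConfig(
                design=two_group_design(1), de_fraction=0.1
            )


class TestReadPositions:
    def test_uniform_mode_fraction_below_500(self):
        cfg = _one_gene_config(1500, math.inf, seed=11)
        models, truth = simulate_gene_models(cfg)
        reads = simulate_read_positions(models, truth, cfg)
        frac = (reads["three_prime_distance_bp"] < 500).mean()
        assert frac == pytest.approx(1 / 3, abs=0.02)

    def test_exponential_window_fraction_matches_integration_oracle(self):
        lam, L = 500.0, 1500
        cfg = _one_gene_config(L, lam, reads=80_000, seed=12)
        models, truth = simulate_gene_models(cfg)
        reads = simulate_read_positions(models, truth, cfg)
        # oracle: numerical integration of the stated truncated density
        density = lambda d: math.exp(-d / lam)
        expected = quad(density, 0, 500)[0] / quad(density, 0, L)[0]
        assert expected == pytest.approx((1 - math.e ** -1) / (1 - math.e ** -3), abs=1e-12)
        frac = (reads["three_prime_distance_bp"] < 500).mean()
        assert frac == pytest.approx(expected, abs=0.01)

    def test_short_transcript_entirely_within_window(self):
        cfg = _one_gene_config(400, 800.0, seed=13)
        models, truth = simulate_gene_models(cfg)
        reads = simulate_read_positions(models, truth, cfg)
        assert (reads["three_prime_distance_bp"] < 400).all()
        assert (reads["three_prime_distance_bp"] < 500).all()

    def test_distances_below_spliced_length(self):
        cfg = SimulationConfig(
            design=two_group_design(), n_genes=100, reads_per_sample=20_000, seed=14
        )
        models, truth = simulate_gene_models(cfg)
        reads = simulate_read_positions(models, truth, cfg)
        lengths = truth.genes["length_bp"]
        assert (
            reads["three_prime_distance_bp"].to_numpy()
            < lengths.loc[reads["gene_id"]].to_numpy()
        ).all()

    def test_read_level_and_closed_form_counts_agree_in_expectation(self):
        cfg = SimulationConfig(
            design=two_group_design(), n_genes=300, reads_per_sample=60_000,
            dispersion=0.0, seed=15,
        )
        models, truth = simulate_gene_models(cfg)
        reads = simulate_read_positions(models, truth, cfg)
        for window in (None, 500):
            mode = "full_length" if window is None else "truncated_500"
            obs = count_reads_in_window(reads, models, window).counts
            exp = expected_counts(truth, cfg, mode)
            z = (obs - exp) / np.sqrt(exp.clip(lower=1.0))
            # Poisson standardized residuals: mean 0, variance ~1
            assert abs(float(z.to_numpy().mean())) < 0.05
            assert float(z.to_numpy().var()) == pytest.approx(1.0, abs=0.25)


class TestCounts:
    def test_poisson_limit_variance_equals_mean(self):
        cfg = SimulationConfig(
            design=two_group_design(), n_genes=2000, reads_per_sample=100_000,
            dispersion=0.0, seed=21,
        )
        _, truth = simulate_gene_models(cfg)
        cm = simulate_counts(truth, cfg, "full_length")
        exp = expected_counts(truth, cfg, "full_length")
        z = (cm.counts - exp) / np.sqrt(exp.clip(lower=1.0))
        assert float(z.to_numpy().var()) == pytest.approx(1.0, abs=0.05)

    def test_null_symmetry_equal_decay_gives_zero_log2fc(self):
        cfg = SimulationConfig(
            design=two_group_design(3, 2000.0, 2000.0), n_genes=800,
            reads_per_sample=100_000, dispersion=0.05, seed=22,
        )
        _, truth = simulate_gene_models(cfg)
        cm = simulate_counts(truth, cfg, "full_length")
        cpm = cm.cpm()  # depths are jittered by design; compare on CPM
        m1 = cpm.iloc[:, :3].mean(axis=1)
        m2 = cpm.iloc[:, 3:].mean(axis=1)
        lfc = np.log2((m2 + 0.5) / (m1 + 0.5))
        assert abs(float(lfc.mean())) < 0.05
        # noise shrinks with baseline mean
        strong = truth.genes["baseline_mean"] > 300
        weak = truth.genes["baseline_mean"] < 50
        assert lfc[strong].abs().mean() < lfc[weak].abs().mean()

    def test_confounded_null_log2fc_matches_closed_form(self):
        """lambda 4000 vs 800 full-length bias equals the window-integral ratio."""
        cfg = SimulationConfig(
            design=two_group_design(3, 4000.0, 800.0), n_genes=600,
            reads_per_sample=200_000, dispersion=0.0,
            baseline_mean_range=(200.0, 600.0), seed=23,
        )
        _, truth = simulate_gene_models(cfg)
        cm = simulate_counts(truth, cfg, "full_length")
        libs = cm.counts.sum(axis=0)
        cpm = cm.counts / libs * 1e6
        lfc_obs = np.log2(cpm.iloc[:, 3:].mean(axis=1) / cpm.iloc[:, :3].mean(axis=1))
        L = truth.genes["length_bp"].to_numpy().astype(float)
        closed = np.log2(window_retention(L, 800.0, None) / window_retention(L, 4000.0, None))
        resid = lfc_obs.to_numpy() - closed
        # equality up to the common normalization constant, gene by gene
        assert np.std(resid) < 0.12
        assert np.corrcoef(lfc_obs, closed)[0, 1] > 0.95

    def test_library_sums_near_target(self):
        cfg = SimulationConfig(
            design=two_group_design(), n_genes=1000, reads_per_sample=100_000,
            dispersion=0.1, seed=24,
        )
        _, truth = simulate_gene_models(cfg)
        cm = simulate_counts(truth, cfg, "full_length")
        targets = target_library_sizes(cfg)
        rel = (cm.counts.sum(axis=0) - targets) / targets
        assert (rel.abs() < 0.05).all()

    def test_truncated_counts_length_independent_when_intact(self):
        """All L >= 500 and lambda >= L: the 500 bp window hides length."""
        cfg = SimulationConfig(
            design=two_group_design(3, 20_000.0, 20_000.0), n_genes=2000,
            reads_per_sample=150_000, dispersion=0.05,
            baseline_mean_range=(100.0, 100.0), seed=25,
        )
        _, truth = simulate_gene_models(cfg)
        cm = simulate_counts(truth, cfg, "truncated_500")
        rho = spearmanr(cm.counts.sum(axis=1), truth.genes["length_bp"]).statistic
        assert abs(rho) < 0.05

    def test_fixed_seed_counts_reproducible(self):
        cfg = SimulationConfig(design=two_group_design(), n_genes=50, seed=26)
        _, truth1 = simulate_gene_models(cfg)
        c1 = simulate_counts(truth1, cfg, "truncated_500").counts
        _, truth2 = simulate_gene_models(
            SimulationConfig(design=two_group_design(), n_genes=50, seed=26)
        )
        c2 = simulate_counts(truth2, cfg, "truncated_500").counts
        pd.testing.assert_frame_equal(c1, c2)


class TestCompanions:
    def test_de_flags_count_and_null_means_identical_across_groups(self):
        cfg = SimulationConfig(
            design=two_group_design(), n_genes=400, de_fraction=0.05,
            de_log2fc=2.0, seed=31,
        )
        _, truth = simulate_gene_models(cfg)
        assert int(truth.genes["is_de"].sum()) == round(0.05 * 400)
        mu = expression_means(truth, cfg)
        null = ~truth.genes["is_de"]
        assert np.allclose(mu.loc[null].iloc[:, :3], mu.loc[null].iloc[:, 3:])
        de = truth.genes["is_de"]
        ratio = mu.loc[de].iloc[:, 0] / mu.loc[de].iloc[:, 3]
        assert np.allclose(ratio, 4.0)

    def test_gene_sets_enriched_in_planted_de_genes(self):
        cfg = SimulationConfig(
            design=two_group_design(), n_genes=400, de_fraction=0.1, seed=32
        )
        _, truth = simulate_gene_models(cfg)
        sets = simulate_gene_sets(truth, cfg)
        de = set(truth.genes.index[truth.genes["is_de"]])
        for name, members in sets.items():
            frac = len(set(members) & de) / len(members)
            if name.startswith("SET_DE"):
                assert frac > 0.3
            else:
                assert frac < 0.3
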