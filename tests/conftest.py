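import numpy as np
import pandas as pd
import pytest

from rnadeg.gene_models import Exon, GeneModel, Transcript
from rnadeg.simulate import (
    SimulationConfig,
    simulate_gene_models,
    two_group_design,
)


@pytest.fixture(scope="session")
def small_null_sim():
    """Null two-group simulation with equal decay scales (no bias)."""
    cfg = SimulationConfig(
        design=two_group_design(3, decay_a=2000.0, decay_b=2000.0),
        n_genes=500,
        reads_per_sample=50_000,
        dispersion=0.1,
        seed=101,
    )
    models, truth = simulate_gene_models(cfg)
    return cfg, models, truth


@pytest.fixture(scope="session")
def confounded_null_sim():
    """Null simulation with unequal decay (the motivating failure mode)."""
    cfg = SimulationConfig(
        design=two_group_design(3, decay_a=4000.0, decay_b=800.0),
        n_genes=2000,
        reads_per_sample=200_000,
        dispersion=0.1,
        seed=202,
    )
    models, truth = simulate_gene_models(cfg)
    return cfg, models, truth


@pytest.fixture
def two_exon_plus():
    """+ strand transcript, exons (100,400)+(600,900), spliced length 600."""
    return Transcript(
        "tx+",
        [Exon("chr1", 100, 400, "+"), Exon("chr1", 600, 900, "+")],
        abundance=1.0,
    )


@pytest.fixture
def two_exon_minus():
    return Transcript(
        "tx-",
        [Exon("chr1", 100, 400, "-"), Exon("chr1", 600, 900, "-")],
        abundance=1.0,
    )


def random_transcript(rng: np.random.Generator, tid: str = "t") -> Transcript:
    """Random multi-exon transcript for property tests."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        width = int(rng.integers(1, 700))
        exons.append(Exon("chrT", pos, pos + width, strand))
        pos += width + int(rng.integers(10, 300))
    return Transcript(tid, exons, abundance=float(rng.uniform(0.1, 5)))


@pytest.fixture
def read_table():
    """Hand-made table of 6 reads over two genes."""
    return pd.DataFrame(
        {
            "sample_id": ["s1"] * 6,
            "gene_id": ["g1", "g1", "g1", "g1", "g2", "g2"],
            "transcript_id": ["g1.t1"] * 4 + ["g2.t1"] * 2,
            "three_prime_distance_bp": [10.0, 499.0, 500.0, 900.0, 0.0, 5.0],
        }
    )
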