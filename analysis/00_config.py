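"""Shared configuration for the numbered analysis drivers.

One demo dataset drives scripts 01-06: the full factorial design
(2 genotypes x 2 sexes x 3 ages x 3 replicates) at desk scale, with 5%
of genes spiked 4-fold in the transgenic samples and per-library decay
scales drawn in 800-4000 bp.  Script 07 runs its own confounded-null
comparison.  All outputs land under results/.
"""

from pathlib import Path

from rnadeg.pipeline import demo_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def analysis_config():
    cfg = demo_config(seed=SEED, n_genes=1000)
    cfg.reads_per_sample = 50_000
    cfg.de_fraction = 0.05
    cfg.de_log2fc = 2.0
    return cfg
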