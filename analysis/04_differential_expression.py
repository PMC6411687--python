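"""Exact-test differential expression for the four old-vs-young contrasts.

For each genotype x sex stratum: round pseudo-counts, estimate the common
NB dispersion, run the conditional exact test, attach BH FDR, apply the
|log2FC| > 2 & p < 0.05 threshold and intersect the four DE lists
(Venn regions).
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfgmod = importlib.import_module("00_config")

from rnadeg.de import intersect_de_sets, run_contrast, threshold_de
from rnadeg.normalization import NormalizationResult


def main() -> None:
    cfg = cfgmod.analysis_config()
    out = cfgmod.RESULTS / "de"
    out.mkdir(parents=True, exist_ok=True)

    pseudo = pd.read_csv(
        cfgmod.RESULTS / "norm" / "pseudo_counts.tsv", sep="\t", index_col="gene_id"
    )
    design = pd.read_csv(
        cfgmod.RESULTS / "data" / "design.tsv", sep="\t", index_col="sample_id"
    )
    norm = NormalizationResult(
        factors=pd.DataFrame(1.0, index=[0], columns=pseudo.columns),
        bins=pd.Series(0, index=pseudo.index),
        pseudo=pseudo,
        effective_lib_size=float(pseudo.sum(axis=0).mean()),
        covariate="precomputed",
    )

    venn_sets = {}
    minfc, maxp = cfg.thresholds[cfg.venn_threshold]
    for contrast in cfg.contrasts:
        res = run_contrast(norm, design, contrast)
        table = res.table.copy()
        table.index.name = "gene_id"
        table.to_csv(out / f"{contrast.name}.tsv", sep="\t", float_format="%.6g")
        passed = threshold_de(res, minfc, maxp)
        venn_sets[contrast.name] = set(passed.index)
        print(
            f"{contrast.name}: phi = {res.phi:.3f}, "
            f"{int((table['pvalue'] < 0.05).sum())} genes at p < 0.05, "
            f"{len(passed)} pass |log2FC| >= {minfc} & p < {maxp}"
        )

    venn_sets.pop("Tg_vs_NTg", None)  # Venn compares the four age contrasts
    venn = intersect_de_sets(venn_sets)
    venn.to_csv(out / "venn_regions.tsv", sep="\t", index=False)
    allway = venn[venn["region"] == "&".join(venn_sets)]
    n_all = int(allway["n_genes"].iloc[0]) if len(allway) else 0
    print(f"genes shared by all four DE lists: {n_all} -> {out}")


if __name__ == "__main__":
    main()
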