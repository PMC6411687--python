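"""Relative qPCR quantification by the 2^-ddCt method.

Expression of a target gene relative to reference genes (here typically
act5c and tub84B) and to a control group: technical replicates are
averaged, dCt = Ct_target - mean(Ct_references), ddCt subtracts the
control-group mean dCt, and the expression ratio is 2^-ddCt.  Using the
arithmetic mean of the two reference Cts is equivalent to normalizing by
the geometric mean of their expression levels.  Group differences are
assessed nonparametrically (Mann-Whitney for independent groups,
Wilcoxon signed-rank for paired designs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["validate_ct_table", "delta_delta_ct", "DdCtResult", "rank_test"]

EXACT_MAX_N = 12  # exact enumeration up to this group size, normal approx beyond


def validate_ct_table(cts: pd.DataFrame, reference_genes) -> None:
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(cts.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (cts["ct"] <= 0).any():
        raise ValueError("all Ct values must be > 0")
    per_sample = cts.groupby("sample_id")["gene"].agg(set)
    for ref in reference_genes:
        lacking = [s for s, genes in per_sample.items() if ref not in genes]
        if lacking:
            raise ValueError(
                f"reference gene {ref!r} missing in sample(s): {', '.join(lacking)}"
            )


@dataclass
class DdCtResult:
    """Per-sample relative expression and the treated-group summary."""

    target: str
    per_sample: pd.DataFrame  # sample_id, group, dct, ddct, ratio
    group_ratio: float  # geometric mean of treated ratios
    control_group: str


def delta_delta_ct(
    cts: pd.DataFrame,
    target: str,
    reference_genes=("act5c", "tub84B"),
    control_group: str = "control",
) -> DdCtResult:
    """2^-ddCt relative expression of ``target`` against the references.

    ``cts`` is long-format with columns sample_id, group, gene, ct (one
    row per technical replicate).  Technical replicates are averaged
    before any differencing.  The control group's ratios have geometric
    mean 1 by construction; the reported group ratio is the geometric
    mean over the non-control samples.
    """
    validate_ct_table(cts, reference_genes)
    mean_ct = (
        cts.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    wide = mean_ct.pivot_table(index=["sample_id", "group"], columns="gene", values="ct")
    if target not in wide.columns or wide[target].isna().any():
        bad = (
            list(wide.index.get_level_values(0)[wide[target].isna()])
            if target in wide.columns
            else list(wide.index.get_level_values(0))
        )
        raise ValueError(f"target gene {target!r} missing in sample(s): {bad}")
    groups = wide.index.get_level_values("group")
    if control_group not in set(groups):
        raise ValueError(f"no samples in control group {control_group!r}")
    ref_ct = wide[list(reference_genes)].mean(axis=1)
    dct = wide[target] - ref_ct
    ddct = dct - dct[groups == control_group].mean()
    ratio = 2.0 ** (-ddct)
    out = pd.DataFrame(
        {
            "sample_id": wide.index.get_level_values("sample_id"),
            "group": groups,
            "dct": dct.to_numpy(),
            "ddct": ddct.to_numpy(),
            "ratio": ratio.to_numpy(),
        }
    )
    treated = out.loc[out["group"] != control_group, "ratio"]
    group_ratio = float(np.exp(np.log(treated).mean())) if len(treated) else float("nan")
    return DdCtResult(target, out, group_ratio, control_group)


def rank_test(treated, control, paired: bool = False) -> float:
    """Nonparametric two-sided group comparison of expression ratios.

    Mann-Whitney U for independent groups, Wilcoxon signed-rank for
    paired data.  Exact enumeration when both groups have <= 12 values
    and no ties bind; normal approximation with tie correction otherwise.
    """
    x = np.asarray(treated, dtype=float)
    y = np.asarray(control, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal-length groups")
        if len(x) < 3:
            raise ValueError("paired test needs >=3 pairs")
        diffs = x - y
        if np.all(diffs == 0):
            return 1.0
        method = "exact" if len(x) <= EXACT_MAX_N and not _has_ties(np.abs(diffs)) else "approx"
        return float(stats.wilcoxon(x, y, alternative="two-sided", method=method).pvalue)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("unpaired test needs >=3 values per group")
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    exact_ok = (
        max(len(x), len(y)) <= EXACT_MAX_N and not _has_ties(np.concatenate([x, y]))
    )
    method = "exact" if exact_ok else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)
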