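"""Negative-binomial exact-test differential expression on pseudo-counts.

The test compares two groups of replicate libraries gene by gene.  After
normalization every sample sits on a common effective library size, so
within a group the replicate counts of a null gene are i.i.d.
NB(mu, phi) and the group sum is NB with mean ``n*mu`` and dispersion
``phi/n``.  Conditioning on the two-group total removes the nuisance
mean, and the two-sided p-value sums the conditional probabilities of
every split as extreme as (i.e. with joint probability no larger than)
the observed one.  At ``phi = 0`` the conditional law is binomial.

The common dispersion ``phi`` is estimated by conditional maximum
likelihood over genes, maximized by golden-section search on
``log(phi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .normalization import NormalizationResult

__all__ = [
    "DispersionEstimate",
    "Contrast",
    "DEResult",
    "estimate_common_dispersion",
    "nb_exact_test",
    "exact_test_pvalue",
    "bh_adjust",
    "run_contrast",
    "threshold_de",
    "intersect_de_sets",
]

PHI_BOUNDS = (1e-4, 5.0)
#: Above this two-group total the split enumeration switches to a normal
#: approximation of the conditional law (continuity-corrected).
ENUMERATION_CAP = 5000


# ---------------------------------------------------------------------------
# Common dispersion: conditional maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    """Common NB dispersion with its conditional log-likelihood."""

    phi: float
    log_likelihood: float
    search_interval: tuple[float, float] = PHI_BOUNDS


def _group_conditional_loglik(y: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene conditional log-likelihood of one replicate group.

    ``y`` is genes x replicates; the likelihood conditions on each gene's
    group total, which removes the gene's mean from the model.
    """
    n = y.shape[1]
    r = 1.0 / phi
    z = y.sum(axis=1)
    return (
        gammaln(y + r).sum(axis=1)
        + gammaln(n * r)
        - gammaln(z + n * r)
        - n * gammaln(r)
    )


def estimate_common_dispersion(
    pseudo: pd.DataFrame,
    groups: list[list[str]],
    bounds: tuple[float, float] = PHI_BOUNDS,
    tol: float = 1e-6,
) -> DispersionEstimate:
    """Maximize the summed conditional likelihood over all genes/groups.

    ``pseudo`` must be integer-valued equalized pseudo-counts; ``groups``
    lists the sample columns of each replicate group (groups of fewer
    than 2 samples carry no dispersion information and are rejected).
    Golden-section search on ``log(phi)`` within ``bounds``.
    """
    if pseudo.empty:
        raise ValueError("empty pseudo-count matrix")
    mats = []
    for g in groups:
        if len(g) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        m = pseudo[list(g)].to_numpy(dtype=float)
        m = m[m.sum(axis=1) > 0]  # all-zero genes contribute exactly 0
        if m.size:
            mats.append(m)
    if not mats:
        raise ValueError("no genes with nonzero counts in any group")

    def objective(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return float(sum(_group_conditional_loglik(m, phi).sum() for m in mats))

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = objective(c), objective(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = objective(d)
    log_opt = (a + b) / 2.0
    # The likelihood can be monotone decreasing in phi (no overdispersion
    # evidence); the search then settles at the lower bound.
    for edge in (lo, hi):
        if objective(edge) > max(fc, fd):
            log_opt = edge
    phi = float(np.exp(log_opt))
    return DispersionEstimate(phi, objective(log_opt), bounds)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _sum_logpmf(x: np.ndarray, mean: float, phi_over_n: float) -> np.ndarray:
    """log pmf of a group-sum count at its NB (or Poisson) law."""
    if phi_over_n == 0.0:
        return x * np.log(mean) - mean - gammaln(x + 1.0)
    r = 1.0 / phi_over_n
    log_p = np.log(r) - np.log(r + mean)
    log_q = np.log(mean) - np.log(r + mean)
    return gammaln(x + r) - gammaln(r) - gammaln(x + 1.0) + r * log_p + x * log_q


def exact_test_pvalue(
    a: float,
    b: float,
    n1: int,
    n2: int,
    phi: float,
    max_enumeration: int | None = ENUMERATION_CAP,
) -> float:
    """Two-sided conditional exact p-value for group sums ``(a, b)``.

    Sums the conditional probabilities of all splits of ``s = a + b``
    whose joint probability does not exceed the observed one (up to a
    1 + 1e-7 relative tolerance so exact ties are kept).  For totals
    above ``max_enumeration`` a continuity-corrected normal approximation
    of the conditional distribution is used.
    """
    a, b = float(round(a)), float(round(b))
    s = a + b
    if s == 0:
        return 1.0
    mu = s / (n1 + n2)
    m1, m2 = n1 * mu, n2 * mu
    if max_enumeration is not None and s > max_enumeration:
        v1 = m1 + (phi / n1) * m1 ** 2
        v2 = m2 + (phi / n2) * m2 ** 2
        sd = np.sqrt(v1 * v2 / (v1 + v2))
        z_hi = (a - m1 - 0.5) / sd
        z_lo = (a - m1 + 0.5) / sd
        p = 2.0 * min(norm.sf(z_hi), norm.cdf(z_lo))
        return float(min(1.0, max(p, 0.0)))
    grid = np.arange(0.0, s + 1.0)
    lp = _sum_logpmf(grid, m1, phi / n1) + _sum_logpmf(s - grid, m2, phi / n2)
    lp_obs = lp[int(a)]
    keep = lp <= lp_obs + np.log1p(1e-7)
    return float(np.exp(logsumexp(lp[keep]) - logsumexp(lp)))


def nb_exact_test(
    pseudo: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    phi: float,
    max_enumeration: int | None = ENUMERATION_CAP,
) -> pd.Series:
    """Per-gene two-sided exact-test p-values, group 2 vs group 1."""
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a = pseudo[list(group1)].sum(axis=1).round()
    b = pseudo[list(group2)].sum(axis=1).round()
    n1, n2 = len(group1), len(group2)
    pvals = [
        exact_test_pvalue(ai, bi, n1, n2, phi, max_enumeration)
        for ai, bi in zip(a.to_numpy(), b.to_numpy())
    ]
    return pd.Series(pvals, index=pseudo.index, name="pvalue")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    """Two disjoint sample groups defined by design-table selectors.

    Each selector maps design columns to a required value (or list of
    values); e.g. ``{"age": "old", "sex": "F"}`` vs ``{"age": "young",
    "sex": "F"}`` contrasts old vs young females.  Fold changes are
    reported as group2 over group1.
    """

    name: str
    group1: dict[str, object]
    group2: dict[str, object]

    def _select(self, design: pd.DataFrame, selector: dict) -> list[str]:
        mask = pd.Series(True, index=design.index)
        for col, wanted in selector.items():
            if col not in design.columns:
                raise ValueError(f"contrast {self.name}: unknown design column {col!r}")
            allowed = wanted if isinstance(wanted, (list, tuple, set)) else [wanted]
            mask &= design[col].isin(list(allowed))
        return list(design.index[mask])

    def resolve(self, design: pd.DataFrame) -> tuple[list[str], list[str]]:
        g1, g2 = self._select(design, self.group1), self._select(design, self.group2)
        if set(g1) & set(g2):
            raise ValueError(f"contrast {self.name}: groups overlap")
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(
                f"contrast {self.name}: each group needs >=2 samples "
                f"(got {len(g1)} and {len(g2)})"
            )
        return g1, g2


@dataclass
class DEResult:
    """Per-gene contrast results: log2FC, logCPM, p, BH FDR."""

    contrast: str
    table: pd.DataFrame  # columns: log2fc, logcpm, pvalue, fdr
    phi: float
    groups: tuple[list[str], list[str]] = field(default=([], []))


def run_contrast(
    norm: NormalizationResult,
    design: pd.DataFrame,
    contrast: Contrast,
    phi: float | None = None,
    max_enumeration: int | None = ENUMERATION_CAP,
) -> DEResult:
    """Exact-test DE for one contrast on normalized pseudo-counts.

    Pseudo-counts are rounded half-to-even for the dispersion estimate
    and the exact test; log2FC uses the unrounded group means with a 0.5
    prior count.  ``phi=None`` estimates the common dispersion from the
    two groups.
    """
    g1, g2 = contrast.resolve(design)
    pseudo = norm.pseudo[g1 + g2]
    rounded = np.rint(pseudo)  # half-to-even
    if phi is None:
        phi = estimate_common_dispersion(rounded, [g1, g2]).phi
    pvals = nb_exact_test(rounded, g1, g2, phi, max_enumeration)
    mean1 = pseudo[g1].mean(axis=1)
    mean2 = pseudo[g2].mean(axis=1)
    log2fc = np.log2((mean2 + 0.5) / (mean1 + 0.5))
    avg_cpm = ((pseudo.mean(axis=1) + 0.5) / norm.effective_lib_size) * 1e6
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "logcpm": np.log2(avg_cpm),
            "pvalue": pvals,
            "fdr": bh_adjust(pvals.to_numpy()),
        },
        index=pseudo.index,
    )
    return DEResult(contrast.name, table, float(phi), (g1, g2))


def threshold_de(
    result: DEResult,
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Genes passing both the fold-change and significance cutoffs.

    Returns the passing rows with a ``direction`` column (up/down,
    group2 relative to group1).  ``use_fdr`` applies ``max_p`` to the BH
    FDR instead of the raw p-value.
    """
    t = result.table
    sig = t["fdr"] < max_p if use_fdr else t["pvalue"] < max_p
    keep = t[(t["log2fc"].abs() >= min_abs_log2fc) & sig].copy()
    keep["direction"] = np.where(keep["log2fc"] > 0, "up", "down")
    return keep


def intersect_de_sets(named_sets: dict[str, set]) -> pd.DataFrame:
    """Venn partition of >=2 named gene sets.

    Returns one row per non-empty region: a boolean membership column
    per set, a ``region`` label (``A&B`` style), and the gene count.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    names = list(named_sets)
    universe = sorted(set().union(*named_sets.values()))
    member = pd.DataFrame(
        {nm: [g in named_sets[nm] for g in universe] for nm in names},
        index=pd.Index(universe, name="gene_id"),
    )
    rows = []
    for pattern, grp in member.groupby(names, sort=False):
        inside = [nm for nm, flag in zip(names, pattern) if flag]
        rows.append(
            dict(
                zip(names, pattern),
                region="&".join(inside) if inside else "(none)",
                n_genes=len(grp),
                genes=";".join(grp.index),
            )
        )
    out = pd.DataFrame(rows).sort_values("region").reset_index(drop=True)
    return out
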