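"""Gene-set over-representation by Fisher tests over multiple top lists.

Instead of fixing one significance cutoff, the enrichment scan takes the
top 50/100/200/500/1000 up- and down-regulated genes (restricted to
p < 0.05), runs a one-sided Fisher (hypergeometric upper-tail) test for
each list against the pre-filtered expression background, and merges the
per-list results into one minimum p-value per set and direction.

The merged minimum is *not* corrected for trying five list sizes and is
anti-conservative by construction; a Bonferroni-across-lists companion
column is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import DEResult

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "fisher_enrichment",
    "toplist_enrichment",
    "merge_toplists",
]

logger = logging.getLogger(__name__)

TOP_SIZES = (50, 100, 200, 500, 1000)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {i}: expected >=3 tab-separated fields")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe.

    The universe is the pre-filtered expressed gene list; set members
    outside it are dropped, and sets left empty are discarded with a
    warning.
    """

    sets: dict[str, set]
    universe: list[str]

    @classmethod
    def from_sets(cls, sets: dict[str, list[str]], universe) -> "GeneSetCollection":
        uni = list(dict.fromkeys(universe))
        uset = set(uni)
        kept: dict[str, set] = {}
        for name, members in sets.items():
            inter = set(members) & uset
            if inter:
                kept[name] = inter
            else:
                logger.warning("gene set %s has no members in the universe; dropped", name)
        return cls(kept, uni)


def fisher_enrichment(
    hits: set, gene_set: set, universe: list[str] | set
) -> tuple[float, tuple[int, int, int, int]]:
    """One-sided over-representation test of ``hits`` in ``gene_set``.

    Returns the hypergeometric upper-tail probability ``P(X >= k)`` for
    overlap ``k`` given universe size ``N``, set size ``K`` (within the
    universe) and list size ``n``, plus the 2x2 table
    ``(k, n - k, K - k, N - K - n + k)``.
    """
    uni = set(universe)
    if not set(hits) <= uni:
        raise ValueError("hits must be a subset of the universe")
    k_set = set(gene_set) & uni
    n_total, k_size, n_hits = len(uni), len(k_set), len(hits)
    k = len(set(hits) & k_set)
    p = float(hypergeom.sf(k - 1, n_total, k_size, n_hits))
    return min(p, 1.0), (k, n_hits - k, k_size - k, n_total - k_size - n_hits + k)


def ranked_gene_list(res: DEResult, direction: str, max_p: float = 0.05) -> list[str]:
    """Significant genes of one direction, ranked for top-list slicing.

    Ascending p, ties by |log2FC| descending, then gene id.
    """
    t = res.table
    sign = t["log2fc"] > 0 if direction == "up" else t["log2fc"] < 0
    sig = t[(t["pvalue"] < max_p) & sign]
    order = sorted(
        sig.index, key=lambda g: (sig.at[g, "pvalue"], -abs(sig.at[g, "log2fc"]), g)
    )
    return order


def toplist_enrichment(
    res: DEResult,
    collection: GeneSetCollection,
    top_sizes: tuple[int, ...] = TOP_SIZES,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Fisher scan over top-N lists in both directions, with merged min-p.

    For each direction the candidate list is the significant genes
    (p < ``max_p``) with the matching fold-change sign, ranked by p; each
    top size takes the first ``min(N, available)`` of them.  The
    background universe is the collection's (pre-filtered) universe.
    Returns the long table; see :func:`merge_toplists` for the merge.
    """
    if not collection.universe:
        raise ValueError("empty background universe")
    rows = []
    for direction in ("up", "down"):
        ranked = [g for g in ranked_gene_list(res, direction, max_p) if g in set(collection.universe)]
        if not ranked:
            logger.info(
                "contrast %s: no significant %s-regulated genes; empty enrichment",
                res.contrast,
                direction,
            )
            continue
        for top_n in top_sizes:
            hits = set(ranked[:top_n])
            for name, members in collection.sets.items():
                p, table = fisher_enrichment(hits, members, collection.universe)
                rows.append(
                    {
                        "set": name,
                        "direction": direction,
                        "top_n": top_n,
                        "n_list": len(hits),
                        "overlap": table[0],
                        "set_size": table[0] + table[2],
                        "universe_size": len(collection.universe),
                        "pvalue": p,
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "set",
            "direction",
            "top_n",
            "n_list",
            "overlap",
            "set_size",
            "universe_size",
            "pvalue",
        ],
    )
    return out


def merge_toplists(table: pd.DataFrame) -> pd.DataFrame:
    """Minimum p across top sizes per (set, direction).

    The ``min_p`` column is the merged statistic as reported; it is not
    corrected for the number of list sizes tried, so ``bonferroni_p``
    (``min(1, n_lists * min_p)``) accompanies it as the conservative
    companion.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["set", "direction", "n_lists", "min_p", "best_top_n", "bonferroni_p"]
        )
    rows = []
    for (name, direction), grp in table.groupby(["set", "direction"], sort=True):
        i = grp["pvalue"].idxmin()
        min_p = float(grp.loc[i, "pvalue"])
        rows.append(
            {
                "set": name,
                "direction": direction,
                "n_lists": len(grp),
                "min_p": min_p,
                "best_top_n": int(grp.loc[i, "top_n"]),
                "bonferroni_p": min(1.0, len(grp) * min_p),
            }
        )
    return pd.DataFrame(rows)
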