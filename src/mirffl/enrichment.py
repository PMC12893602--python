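"""Over-representation analysis (ORA) of a DE gene list against gene sets.

One-sided hypergeometric upper-tail test per set (P[X >= overlap]) with
Benjamini-Hochberg adjustment across tested sets; the reported table is
sorted by p and truncated to the significant top-k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ORA_COLUMNS = [
    "set_name", "overlap", "set_size", "list_size", "universe_size",
    "p_value", "adj_p", "overlap_genes",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


def ora(
    de_genes,
    universe,
    sets: list[GeneSet],
    p_thresh: float = 0.05,
    top_k: int | None = 10,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` in each set.

    Sets are intersected with the universe before testing. With
    ``top_k=None`` the full sorted table is returned (no p cutoff),
    otherwise rows are restricted to p < ``p_thresh`` and the first
    ``top_k`` are reported.
    """
    de_genes = set(de_genes)
    universe = set(universe)
    offenders = de_genes - universe
    if offenders:
        raise ValueError(f"DE genes outside the universe: {sorted(offenders)[:10]}")
    M, N = len(universe), len(de_genes)
    rows = []
    for s in sets:
        members = s.members & universe
        if not members:
            continue
        overlap_genes = sorted(members & de_genes)
        n, k = len(members), len(overlap_genes)
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {
                "set_name": s.name,
                "overlap": k,
                "set_size": n,
                "list_size": N,
                "universe_size": M,
                "p_value": min(p, 1.0),
                "overlap_genes": ";".join(overlap_genes),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ORA_COLUMNS)
    table = pd.DataFrame(rows)
    table["adj_p"] = np.maximum(multipletests(table["p_value"], method="fdr_bh")[1],
                                table["p_value"])
    table = table.sort_values(["p_value", "set_name"], ignore_index=True)[ORA_COLUMNS]
    if top_k is not None:
        table = table[table["p_value"] < p_thresh].head(top_k).reset_index(drop=True)
    logger.info("ora: %d sets tested, %d reported", len(rows), len(table))
    return table
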