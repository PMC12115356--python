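"""Gene-set over-representation by the one-sided hypergeometric (Fisher) test.

Database-agnostic: any GMT file of named gene sets works, so the stage runs
hermetically on synthetic sets just as it would on GO slims or pathway
collections.  Significance defaults to BH-adjusted q < 0.05; the classical
family-wise corrections are selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import bh_adjust

__all__ = ["GeneSetCollection", "fisher_enrichment", "load_gmt"]

log = logging.getLogger(__name__)

_CORRECTIONS = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm", "sidak": "sidak"}


@dataclass
class GeneSetCollection:
    """Named gene sets over a finite gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty gene universe")
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"set {name!r} has {len(extra)} member(s) outside the universe"
                )

    @classmethod
    def from_gmt(cls, path, universe: set[str]) -> "GeneSetCollection":
        sets = load_gmt(path)
        clipped = {}
        for name, members in sets.items():
            inside = members & universe
            if len(inside) < len(members):
                log.warning(
                    "set %s: dropped %d member(s) outside the universe",
                    name,
                    len(members) - len(inside),
                )
            clipped[name] = inside
        return cls(clipped, universe)


def load_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file (set name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def fisher_enrichment(
    query, collection: GeneSetCollection, correction: str = "bh"
) -> pd.DataFrame:
    """Over-representation of a query gene list in each collection set.

    p is the upper-tail hypergeometric probability of drawing at least the
    observed overlap when sampling |query| genes from the universe; q is
    the corrected p (BH by default).  Query genes outside the universe are
    dropped with a warning.  Rows are sorted by (p, set name) so results do
    not depend on set iteration order.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    query = set(query)
    outside = query - collection.universe
    if outside:
        log.warning("dropping %d query gene(s) outside the universe", len(outside))
        query &= collection.universe
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        # odds ratio of the 2x2 overlap table (0.5 continuity on empty cells)
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {"set": name, "set_size": K, "overlap": k, "odds": odds, "p": min(p, 1.0)}
        )
    table = pd.DataFrame(rows)
    if len(table):
        if correction == "bh":
            table["q"] = bh_adjust(table["p"].to_numpy())
        else:
            table["q"] = multipletests(
                table["p"].to_numpy(), method=_CORRECTIONS[correction]
            )[1]
        table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return table
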