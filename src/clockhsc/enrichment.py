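"""Hypergeometric gene-set over-representation analysis (ORA).

For a query of n genes drawn from a universe of N, a set with K members
and overlap k scores p = P(X >= k) under Hypergeometric(N, K, n); BH
adjustment runs across all tested terms.  The universe defaults to the
assayed gene annotation, not the union of the GMT, because the background
should reflect what could have been detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from clockhsc.expression import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        if not self.universe:
            self.universe = frozenset().union(
                *(members for _, members in self.sets.values())
            )
        clipped = {}
        for term, (description, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")
            inside = frozenset(members) & self.universe
            dropped = len(members) - len(inside)
            if dropped:
                logger.warning(
                    "term %s: %d members outside the universe dropped", term, dropped
                )
            if not inside:
                raise ValueError(f"gene set {term!r} has no members in the universe")
            clipped[term] = (description, inside)
        self.sets = clipped

    @classmethod
    def from_gmt(cls, sets, universe=()) -> "GeneSetCollection":
        return cls(sets=dict(sets), universe=frozenset(universe))


def hypergeometric_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """Upper-tail P(X >= k) for overlap under the hypergeometric null."""
    return float(min(1.0, stats.hypergeom.sf(k - 1, big_n, big_k, n)))


def enrich(
    query: set[str] | list[str],
    collection: GeneSetCollection,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """ORA of a query gene list against every set in the collection.

    Query ids outside the universe are dropped (count logged).  Sets
    smaller than ``min_set_size`` are reported with ``small_set=True`` and
    excluded from the BH family.  Rows are sorted by (p, term id).
    """
    query_set = set(query)
    inside = query_set & collection.universe
    dropped = len(query_set) - len(inside)
    if dropped:
        logger.warning("%d query ids outside the universe dropped", dropped)
    if not inside:
        raise ValueError("query is empty after restricting to the universe")

    big_n = len(collection.universe)
    n = len(inside)
    records = []
    for term in sorted(collection.sets):
        description, members = collection.sets[term]
        big_k = len(members)
        k = len(inside & members)
        records.append(
            {
                "term": term,
                "description": description,
                "overlap": k,
                "set_size": big_k,
                "query_size": n,
                "universe_size": big_n,
                "p": hypergeometric_tail(k, big_n, big_k, n),
                "small_set": big_k < min_set_size,
            }
        )
    result = pd.DataFrame(records)
    result["fdr"] = np.nan
    tested = ~result["small_set"]
    result.loc[tested, "fdr"] = benjamini_hochberg(result.loc[tested, "p"].to_numpy())
    result = result.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return result
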