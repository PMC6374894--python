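"""Hypergeometric gene-set over-representation with BH correction.

For a query of n genes drawn from a universe of N, a set with K members in
the universe and k of them in the query is scored by the exact upper tail
P(X >= k) of Hypergeometric(N, K, n).  The universe should be the genes the
DEG caller actually tested (not the genome) to avoid platform bias.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_enrich", "hypergeom_upper_tail"]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric parameters k={k} N={N} K={K} n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: Iterable[str],
    sets: dict[str, tuple[str, list[str]]],
    universe: Iterable[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test every gene set for over-representation in the query.

    Query genes outside the universe are dropped (count logged); set sizes K
    are taken after intersecting each set with the universe, and BH runs
    across all sets with K >= 1.  Returns all rows sorted by p with a
    ``significant`` flag at q <= fdr.
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(map(str, query))
    dropped = len(query - universe)
    if dropped:
        logger.info("hypergeom_enrich: dropped %d query gene(s) outside the universe", dropped)
    query &= universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    N, n = len(universe), len(query)
    rows = []
    for set_id in sorted(sets):
        desc, members = sets[set_id]
        in_universe = set(map(str, members)) & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        rows.append((set_id, desc, N, K, n, k, hypergeom_upper_tail(k, N, K, n)))
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    table = pd.DataFrame(rows, columns=["set_id", "description", "N", "K", "n", "k", "p"])
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["q"] <= fdr
    return table.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
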