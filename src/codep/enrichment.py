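"""Over-representation analysis of correlated gene lists.

Given a query list (typically the top-k significant correlates of a
target gene) and a universe (the genes the screen could have returned),
each gene set is scored with the one-sided hypergeometric tail
P(X >= k) — equivalently the one-sided Fisher exact test of the 2x2
overlap table — followed by Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import pandas as pd
from scipy.stats import hypergeom

from codep.correlate import adjust_pvalues
from codep.io import GeneSetCollection

logger = logging.getLogger("codep.enrichment")

ORA_COLUMNS = ["set_id", "description", "k", "K", "n", "N", "p", "q"]


def hypergeom_over_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation p-value P(X >= k).

    ``X ~ Hypergeometric(N, K, n)``: drawing ``n`` query genes from a
    universe of ``N`` containing ``K`` set members, the probability of an
    overlap at least as large as the observed ``k``.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            "(need 0 <= k <= min(K, n) and K, n <= N)"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def top_correlates(
    table: pd.DataFrame,
    target: str,
    q_thresh: float = 0.05,
    k: int | None = None,
) -> list:
    """Ranked significant correlates of a target, self excluded.

    The table's own record order (ascending q, then descending ``|r|``)
    is preserved; ``k`` truncates to the strongest hits.
    """
    sub = table[table["target"] == target]
    if sub.empty:
        raise KeyError(f"target {target!r} not present in correlation table")
    sub = sub[(sub["gene"] != target) & sub["q"].notna() & (sub["q"] < q_thresh)]
    genes = list(sub["gene"])
    return genes if k is None else genes[:k]


def run_ora(
    query: Sequence,
    universe,
    sets: GeneSetCollection,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against gene sets.

    Query genes outside the universe are dropped (with a logged count)
    and duplicates collapsed keeping first occurrence; ``top_k`` then
    truncates the remaining ranked list.  One record is emitted per set
    with a non-empty universe intersection, with BH q-values over all
    emitted p-values, sorted by ascending q (ties by p then set id).
    """
    universe = set(universe)
    seen = set()
    effective = []
    dropped = 0
    for g in query:
        if g in seen:
            continue
        seen.add(g)
        if g in universe:
            effective.append(g)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", dropped)
    if top_k is not None:
        effective = effective[:top_k]
    if not effective:
        raise ValueError("empty query after universe intersection")

    qset = set(effective)
    n = len(effective)
    N = len(universe)
    rows = []
    for sid, gs in sets.items():
        in_universe = gs.members & universe
        if not in_universe:
            continue
        K = len(in_universe)
        k = len(qset & in_universe)
        rows.append(
            {
                "set_id": sid,
                "description": gs.description,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_over_p(k, K, n, N),
            }
        )
    result = pd.DataFrame(rows, columns=ORA_COLUMNS[:-1])
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        return result
    result["q"] = adjust_pvalues(result["p"].to_numpy(), method="BH")
    result = result.sort_values(
        ["q", "p", "set_id"], kind="stable", ignore_index=True
    )
    return result
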