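"""Exact over-representation tests of query gene sets against pathways.

The test is the one-sided hypergeometric tail: given a universe of N genes,
a pathway with K members in that universe, and a query of n genes, the
p-value is P(X >= k) for the observed overlap k, X ~ Hypergeom(N, K, n).
The reported odds ratio is the sample cross-product ratio of the 2x2 table,
with a Haldane +0.5 correction only when a zero cell makes the ratio
undefined. No multiplicity correction is applied by default (the screen is
deliberately permissive); Benjamini-Hochberg q-values are optional.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping

import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .genesets import GeneSetCollection, restrict_to_universe  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

DEFAULT_P_REPORT = 0.15
DEFAULT_GWAS_P = 1.0e-5


def fisher_overlap(
    k: int, query_size: int, set_size: int, universe_size: int
) -> tuple[float, float]:
    """One-sided over-representation p and sample odds ratio.

    The 2x2 table is ``a=k`` (in query & set), ``b=query-k``, ``c=set-k``,
    ``d=universe-query-set+k``. Returns ``(P(X >= k), a*d/(b*c))``; when b or
    c is zero all four cells get +0.5 before forming the ratio, and ``k=0``
    yields an odds ratio of 0.
    """
    a = k
    b = query_size - k
    c = set_size - k
    d = universe_size - query_size - set_size + k
    if min(a, b, c, d) < 0 or query_size > universe_size or set_size > universe_size:
        raise ValueError(
            f"inconsistent 2x2 margins: k={k}, query={query_size}, "
            f"set={set_size}, universe={universe_size}"
        )
    p = float(stats.hypergeom.sf(k - 1, universe_size, set_size, query_size))
    p = min(max(p, 0.0), 1.0)
    if b == 0 or c == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    elif a == 0 or d == 0:
        odds = 0.0 if a == 0 else math.inf
    else:
        odds = a * d / (b * c)
    return p, float(odds)


def enrich_pathways(
    query: Iterable[str],
    pathways: GeneSetCollection,
    universe: Iterable[str],
    p_report: float = DEFAULT_P_REPORT,
    bh: bool = False,
) -> pd.DataFrame:
    """Test every pathway for over-representation of *query* genes.

    Query genes outside the universe are dropped (count logged). Rows are
    sorted by ascending p-value (ties broken by pathway name); rows with
    ``p <= p_report`` carry ``reported=True``.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    dropped = query - universe
    if dropped:
        logger.info("dropped %d query genes outside the universe", len(dropped))
    query &= universe

    restricted = pathways.restrict(universe)
    rows = []
    for name in restricted:
        members = restricted[name]
        overlap = query & members
        p, odds = fisher_overlap(len(overlap), len(query), len(members), len(universe))
        rows.append(
            {
                "set_name": name,
                "k": len(overlap),
                "query_size": len(query),
                "set_size": len(members),
                "universe_size": len(universe),
                "p_value": p,
                "odds_ratio": odds,
                "genes": ";".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.sort_values(
        ["p_value", "set_name"], kind="stable", ignore_index=True
    )
    if bh:
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["reported"] = table["p_value"] <= p_report
    return table


def filter_by_score(
    table: Mapping[str, float], threshold: float = DEFAULT_GWAS_P, keep: str = "le"
) -> frozenset:
    """Genes whose score passes a threshold (e.g. GWAS p <= 1e-5)."""
    if keep == "le":
        return frozenset(g for g, v in table.items() if v <= threshold)
    if keep == "ge":
        return frozenset(g for g, v in table.items() if v >= threshold)
    raise ValueError(f"keep must be 'le' or 'ge', got {keep!r}")
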