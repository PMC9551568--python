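"""Shortest-distance profiles from gene groups to a target set.

For each query gene the statistic is the mean directed unweighted
shortest-path distance to the *reachable* members of a target set
(unreachable targets are excluded from the mean, and the number of
reachable targets is reported so the censoring stays visible). Group
distance distributions are compared with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph import SignalingGraph

logger = logging.getLogger(__name__)

BACKGROUND = "background"


def avg_shortest_distance(
    graph: SignalingGraph,
    gene: str,
    target_set: Iterable[str],
    max_depth: int | None = None,
) -> tuple[float, int]:
    """Mean directed distance from *gene* to reachable targets.

    Returns ``(mean distance, n reachable)``; ``(nan, 0)`` when no target is
    reachable. A gene that is itself a target contributes distance 0 for the
    (gene, gene) pair.
    """
    if gene not in graph:
        raise KeyError(f"gene {gene!r} not in graph")
    targets = frozenset(target_set) & graph.nodes
    if not targets:
        raise ValueError("target set shares no genes with the graph")
    dist = nx.single_source_shortest_path_length(graph.nx, gene, cutoff=max_depth)
    found = [dist[t] for t in targets if t in dist]
    if not found:
        return float("nan"), 0
    return float(np.mean(found)), len(found)


def distance_profiles(
    graph: SignalingGraph,
    groups: Mapping[str, Iterable[str]],
    background: Iterable[str],
    target_set: Iterable[str],
    max_depth: int | None = None,
) -> pd.DataFrame:
    """Per-gene average target distances for named groups plus background.

    The ``background`` group is the supplied background minus the union of
    the query groups. Genes outside the graph are dropped with a logged
    count; genes that reach no target keep ``n_reachable_targets == 0`` and
    a NaN distance (excluded from density comparisons).
    """
    targets = frozenset(target_set)
    if not targets & graph.nodes:
        raise ValueError("empty target set on the graph")
    groups = {name: frozenset(g) for name, g in groups.items()}
    query_union = frozenset().union(*groups.values()) if groups else frozenset()
    all_groups = dict(groups)
    all_groups[BACKGROUND] = frozenset(background) - query_union

    rows = []
    n_dropped = 0
    for name in sorted(all_groups):
        for gene in sorted(all_groups[name]):
            if gene not in graph:
                n_dropped += 1
                continue
            d, n_reach = avg_shortest_distance(graph, gene, targets, max_depth)
            rows.append(
                {
                    "gene": gene,
                    "group": name,
                    "avg_distance": d,
                    "n_reachable_targets": n_reach,
                }
            )
    if n_dropped:
        logger.info("dropped %d profile genes absent from the graph", n_dropped)
    profile = pd.DataFrame(rows, columns=["gene", "group", "avg_distance", "n_reachable_targets"])
    if not profile.empty and (profile["n_reachable_targets"] == 0).all():
        logger.warning("no profiled gene reaches any target")
        return profile.iloc[0:0]
    return profile


def compare_groups(
    profile: pd.DataFrame,
    group_a: str,
    group_b: str,
    method: str = "asymptotic",
) -> dict:
    """Two-sided Mann-Whitney U between two groups' finite distances.

    ``method="asymptotic"`` (default) uses the normal approximation with tie
    correction; ``"exact"`` enumerates the null distribution of U (only
    valid without ties). Returns the U statistic, p-value and both medians.
    """
    vals = {}
    for g in (group_a, group_b):
        sub = profile.loc[
            (profile["group"] == g) & (profile["n_reachable_targets"] > 0),
            "avg_distance",
        ].to_numpy()
        if sub.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 genes with finite distances")
        vals[g] = sub
    res = stats.mannwhitneyu(
        vals[group_a], vals[group_b], alternative="two-sided", method=method
    )
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_a": float(np.median(vals[group_a])),
        "median_b": float(np.median(vals[group_b])),
        "method": method,
    }
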