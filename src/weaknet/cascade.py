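"""Iterative shortest-path inference of signaling cascades.

Given a directed signaling graph, a set of signaling *source* genes (V0,
e.g. upregulated receptors) and a set of signaling *target* genes (V1, e.g.
apoptosis effectors), the algorithm links sources to targets through
minimal directed cascades:

1. for every pair (i, j) in the current V0 x V1 with j reachable from i
   within ``max_depth`` hops, compute the shortest directed path(s);
2. add the nodes and edges of the selected paths to the output network;
3. promote every V1 member that appears on any selected path into V0
   (and remove it from V1);
4. repeat until V1 is empty or no remaining V1 member is reachable.

Remaining V1 members are reported as unreachable. Node roles in the result:
original V0 members are ``source``; genes promoted out of V1 are ``target``;
all other path nodes are ``linker``. Paths are unweighted and
direction-respecting; ALL tied shortest paths are kept by default
(``tie_policy="all"``), with ``"lexicographic-first"`` producing a minimal
network. An undirected fallback exists for very sparse graphs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from .genesets import GeneSetCollection
from .graph import SignalingGraph

logger = logging.getLogger(__name__)

DEFAULT_MAX_DEPTH = 6


@dataclass
class CascadePartition:
    """Canonicalized (V0, V1) node sets restricted to the graph.

    Genes in both sets are assigned to V0; genes absent from the graph are
    dropped. Both adjustments are logged.
    """

    v0: frozenset
    v1: frozenset

    @classmethod
    def from_sets(cls, sources, targets, graph: SignalingGraph) -> "CascadePartition":
        sources, targets = frozenset(sources), frozenset(targets)
        overlap = sources & targets
        if overlap:
            logger.info("%d genes in both V0 and V1 assigned to V0", len(overlap))
            targets -= overlap
        missing = (sources | targets) - graph.nodes
        if missing:
            logger.info("%d partition genes absent from the graph dropped", len(missing))
        return cls(sources & graph.nodes, targets & graph.nodes)


@dataclass
class CascadeNetwork:
    """Inferred subnetwork with node roles and a per-iteration log."""

    roles: dict[str, str]
    edges: frozenset
    iteration_log: list[dict] = field(default_factory=list)
    unreachable_targets: frozenset = frozenset()

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.roles)

    def role_counts(self) -> dict[str, int]:
        counts = {"source": 0, "linker": 0, "target": 0}
        for role in self.roles.values():
            counts[role] += 1
        return counts

    def to_sif_rows(self) -> list[tuple]:
        return sorted((u, "activation", v) for u, v in self.edges)


def _bfs_tree(graph: SignalingGraph, source: str, max_depth: int):
    """BFS layering: distances and shortest-path predecessor lists."""
    dist = {source: 0}
    preds: dict[str, list] = {source: []}
    queue = deque([source])
    g = graph.nx
    while queue:
        u = queue.popleft()
        if dist[u] >= max_depth:
            continue
        for v in g.successors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    return dist, preds


def _unwind(preds: dict, target: str) -> list:
    """Enumerate all shortest paths from the BFS root to *target*."""
    if not preds[target]:
        return [[target]]
    paths = []
    stack = [[target]]
    while stack:
        partial = stack.pop()
        head = partial[0]
        if not preds[head]:
            paths.append(partial)
            continue
        for p in preds[head]:
            stack.append([p] + partial)
    return paths


def all_shortest_paths(
    graph: SignalingGraph, source: str, target: str, max_depth: int = DEFAULT_MAX_DEPTH
) -> list:
    """All minimal-hop directed paths source -> target within *max_depth*.

    Returns ``[]`` when the target is unreachable (or farther than
    *max_depth*); paths are in lexicographic node order for determinism.
    """
    for gene in (source, target):
        if gene not in graph:
            raise KeyError(f"gene {gene!r} not in graph")
    if source == target:
        return [[source]]
    dist, preds = _bfs_tree(graph, source, max_depth)
    if target not in dist:
        return []
    return sorted(_unwind(preds, target))


def infer_cascades(
    graph: SignalingGraph,
    partition: CascadePartition,
    max_depth: int = DEFAULT_MAX_DEPTH,
    tie_policy: str = "all",
) -> CascadeNetwork:
    """Run the iterative source-to-target shortest-path linking algorithm."""
    if tie_policy not in ("all", "lexicographic-first"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    v0, v1 = set(partition.v0), set(partition.v1)
    if not v0 or not v1:
        raise ValueError("V0 and V1 must be non-empty after canonicalization")
    original_v0 = frozenset(v0)

    net_nodes: set = set()
    net_edges: set = set()
    promoted_all: set = set()
    log: list[dict] = []
    max_iter = len(v1) + 1

    for iteration in range(1, max_iter + 1):
        if not v1:
            break
        selected_paths: list = []
        pair_records: list = []
        for s in sorted(v0):
            dist, preds = _bfs_tree(graph, s, max_depth)
            for t in sorted(v1):
                if t == s or t not in dist:
                    continue
                paths = sorted(_unwind(preds, t))
                if tie_policy == "lexicographic-first":
                    paths = paths[:1]
                selected_paths.extend(paths)
                pair_records.append(
                    {"source": s, "target": t, "length": dist[t], "n_paths": len(paths)}
                )
        if not selected_paths:
            break  # nothing in V1 is reachable any more
        promoted = set()
        for path in selected_paths:
            net_nodes.update(path)
            net_edges.update(zip(path[:-1], path[1:]))
            promoted.update(set(path) & v1)
        assert promoted, "selected paths must touch V1"
        v0 |= promoted
        v1 -= promoted
        promoted_all |= promoted
        log.append(
            {
                "iteration": iteration,
                "promoted": sorted(promoted),
                "pairs": pair_records,
            }
        )

    assert len(log) <= len(partition.v1) + 1, "iteration bound exceeded"
    roles = {}
    for n in net_nodes:
        if n in original_v0:
            roles[n] = "source"
        elif n in promoted_all:
            roles[n] = "target"
        else:
            roles[n] = "linker"
    return CascadeNetwork(
        roles=roles,
        edges=frozenset(net_edges),
        iteration_log=log,
        unreachable_targets=frozenset(v1),
    )


def summarize_network(
    net: CascadeNetwork, annotations: GeneSetCollection | None = None
) -> pd.DataFrame:
    """Node/edge/role counts plus per-annotation overlaps, one row each."""
    rows = [
        {"metric": "n_nodes", "value": len(net.nodes), "genes": ""},
        {"metric": "n_edges", "value": len(net.edges), "genes": ""},
        {
            "metric": "n_unreachable_targets",
            "value": len(net.unreachable_targets),
            "genes": ";".join(sorted(net.unreachable_targets)),
        },
    ]
    for role, count in sorted(net.role_counts().items()):
        rows.append({"metric": f"n_{role}", "value": count, "genes": ""})
    if annotations is not None:
        for name in sorted(annotations):
            overlap = annotations[name] & net.nodes
            rows.append(
                {
                    "metric": f"annotation:{name}",
                    "value": len(overlap),
                    "genes": ";".join(sorted(overlap)),
                }
            )
    return pd.DataFrame(rows)
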