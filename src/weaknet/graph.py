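"""Directed signaling graphs over gene symbols.

A :class:`SignalingGraph` wraps a :class:`networkx.DiGraph` whose nodes are
gene symbols and whose edges carry an ``interaction`` label (e.g.
``activation``), together with a pathway -> gene-set annotation. Graphs are
exchanged as SIF edge lists (``source<TAB>interaction<TAB>target``) and can
be exported to GraphML.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

DEFAULT_INTERACTION = "activation"


class SignalingGraph:
    """Directed gene-gene interaction graph with pathway annotation.

    Self-loops are dropped on construction (with a logged count): a gene
    trivially "signals to itself" and such edges carry no cascade
    information.
    """

    def __init__(
        self,
        edges: Iterable[tuple] = (),
        nodes: Iterable[str] = (),
        pathways: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(str(n) for n in nodes)
        n_self = 0
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                label = DEFAULT_INTERACTION
            else:
                u, label, v = edge[0], edge[1], edge[2]
            u, v = str(u), str(v)
            if u == v:
                n_self += 1
                continue
            g.add_edge(u, v, interaction=label)
        if n_self:
            logger.info("dropped %d self-loop edges", n_self)
        self._g = g
        self.pathways: dict[str, frozenset] = {
            name: frozenset(str(x) for x in genes)
            for name, genes in (pathways or {}).items()
        }

    # -- container protocol -------------------------------------------------
    @property
    def nx(self) -> nx.DiGraph:
        return self._g

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._g.nodes)

    def edges(self, data: bool = False):
        return self._g.edges(data=data)

    def edge_set(self) -> frozenset:
        return frozenset((u, v) for u, v in self._g.edges())

    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __repr__(self) -> str:  # pragma: no cover
        return f"SignalingGraph({self.n_nodes()} genes, {self.n_edges()} edges)"

    def reversed(self) -> "SignalingGraph":
        out = SignalingGraph(nodes=self.nodes, pathways=self.pathways)
        for u, v, d in self._g.edges(data=True):
            out._g.add_edge(v, u, **d)
        return out

    def undirected_copy(self) -> "SignalingGraph":
        """Symmetrized graph for the undirected-distance fallback."""
        out = SignalingGraph(nodes=self.nodes, pathways=self.pathways)
        for u, v, d in self._g.edges(data=True):
            out._g.add_edge(u, v, **d)
            out._g.add_edge(v, u, **d)
        return out


def read_sif(path: str | Path, pathways: Mapping[str, Iterable[str]] | None = None) -> SignalingGraph:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"malformed SIF line (want 3 tab fields): {line!r}")
            edges.append((fields[0], fields[1], fields[2]))
    return SignalingGraph(edges, pathways=pathways)


def write_sif(graph: SignalingGraph, path: str | Path) -> None:
    rows = sorted(
        (u, d.get("interaction", DEFAULT_INTERACTION), v)
        for u, v, d in graph.nx.edges(data=True)
    )
    with open(path, "w") as fh:
        for u, label, v in rows:
            fh.write(f"{u}\t{label}\t{v}\n")


def write_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
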