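"""Shortest-path enumeration and the iterative source-target linking rule."""

import itertools

import numpy as np
import pytest

import weaknet as wn
from weaknet.cascade import CascadePartition
from weaknet.graph import SignalingGraph

from conftest import random_digraph


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def enumerate_min_paths(graph: SignalingGraph, source, target, max_depth):
    """Exhaustive simple-path enumeration keeping only minimal lengths."""
    best: list = []
    best_len = max_depth + 1
    stack = [[source]]
    while stack:
        path = stack.pop()
        head = path[-1]
        if head == target and len(path) > 1:
            length = len(path) - 1
            if length < best_len:
                best, best_len = [path], length
            elif length == best_len:
                best.append(path)
            continue
        if len(path) - 1 >= best_len or len(path) - 1 >= max_depth:
            continue
        for nxt in graph.nx.successors(head):
            if nxt not in path:
                stack.append(path + [nxt])
    return sorted(best)


def infer_cascades_oracle(graph, v0, v1, max_depth=6):
    """Literal re-execution of the promotion rule with brute-force paths."""
    v0, v1 = set(v0), set(v1)
    edges = set()
    iterations = 0
    while v1:
        iterations += 1
        selected = []
        for s in sorted(v0):
            for t in sorted(v1):
                if s != t:
                    selected.extend(enumerate_min_paths(graph, s, t, max_depth))
        promoted = set()
        for path in selected:
            edges.update(zip(path[:-1], path[1:]))
            promoted.update(set(path) & v1)
        if not promoted:
            break
        v0 |= promoted
        v1 -= promoted
    return frozenset(edges), frozenset(v1), iterations


# ---------------------------------------------------------------------------
# all_shortest_paths
# ---------------------------------------------------------------------------

class TestAllShortestPaths:
    def test_chain(self, chain_graph):
        assert wn.all_shortest_paths(chain_graph, "A", "C") == [["A", "B", "C"]]

    def test_diamond_returns_both_tied_paths(self, diamond_graph):
        assert wn.all_shortest_paths(diamond_graph, "A", "D") == [
            ["A", "B", "D"],
            ["A", "C", "D"],
        ]

    def test_unreachable_and_depth_limit(self, chain_graph):
        assert wn.all_shortest_paths(chain_graph, "C", "A") == []
        assert wn.all_shortest_paths(chain_graph, "A", "C", max_depth=1) == []

    def test_missing_gene_named_in_error(self, chain_graph):
        with pytest.raises(KeyError, match="ZZ"):
            wn.all_shortest_paths(chain_graph, "A", "ZZ")

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_enumeration_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_digraph(rng, 12, 0.15)
        nodes = sorted(graph.nodes)
        for source, target in itertools.islice(
            itertools.permutations(nodes, 2), 0, 40
        ):
            got = wn.all_shortest_paths(graph, source, target, max_depth=5)
            assert got == enumerate_min_paths(graph, source, target, 5)


# ---------------------------------------------------------------------------
# infer_cascades
# ---------------------------------------------------------------------------

class TestInferCascades:
    def test_single_edge(self):
        graph = SignalingGraph([("A", "B")])
        part = CascadePartition.from_sets({"A"}, {"B"}, graph)
        net = wn.infer_cascades(graph, part)
        assert net.edges == {("A", "B")}
        assert net.roles == {"A": "source", "B": "target"}
        assert len(net.iteration_log) == 1

    def test_chain_promotes_both_targets_in_one_iteration(self, chain_graph):
        """V1 genes on any selected shortest path are promoted together."""
        part = CascadePartition.from_sets({"A"}, {"B", "C"}, chain_graph)
        net = wn.infer_cascades(chain_graph, part)
        assert net.edges == {("A", "B"), ("B", "C")}
        assert net.roles["B"] == "target" and net.roles["C"] == "target"
        assert len(net.iteration_log) == 1
        assert sorted(net.iteration_log[0]["promoted"]) == ["B", "C"]

    def test_unreachable_target_is_reported(self):
        graph = SignalingGraph([("A", "B")], nodes=["A", "B", "Z"])
        part = CascadePartition.from_sets({"A"}, {"Z"}, graph)
        net = wn.infer_cascades(graph, part)
        assert net.edges == frozenset()
        assert net.unreachable_targets == {"Z"}
        assert len(net.iteration_log) == 0

    def test_second_iteration_links_via_promoted_target(self):
        # with max_depth 2, C is out of A's reach until B is promoted
        graph = SignalingGraph([("A", "B"), ("B", "X"), ("X", "C")])
        part = CascadePartition.from_sets({"A"}, {"B", "C"}, graph)
        net = wn.infer_cascades(graph, part, max_depth=2)
        assert len(net.iteration_log) == 2
        assert net.iteration_log[0]["promoted"] == ["B"]
        assert net.iteration_log[1]["promoted"] == ["C"]
        assert net.roles["X"] == "linker"
        assert net.unreachable_targets == frozenset()

    def test_empty_partition_rejected(self, chain_graph):
        with pytest.raises(ValueError):
            wn.infer_cascades(
                chain_graph, CascadePartition(frozenset(), frozenset({"C"}))
            )

    def test_overlap_genes_assigned_to_sources(self, chain_graph):
        part = CascadePartition.from_sets({"A", "B"}, {"B", "C"}, chain_graph)
        assert part.v0 == {"A", "B"}
        assert part.v1 == {"C"}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_promotion_rule_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(100 + seed)
        graph = random_digraph(rng, 10, 0.18)
        nodes = sorted(graph.nodes)
        v0 = set(nodes[:2])
        v1 = set(nodes[-3:])
        part = CascadePartition.from_sets(v0, v1, graph)
        net = wn.infer_cascades(graph, part, max_depth=6)
        edges, unreachable, _ = infer_cascades_oracle(graph, part.v0, part.v1, 6)
        assert net.edges == edges
        assert net.unreachable_targets == unreachable
        assert len(net.iteration_log) <= len(part.v1) + 1

    def test_result_invariant_to_input_order(self):
        rng = np.random.default_rng(200)
        graph = random_digraph(rng, 10, 0.2)
        edges = list(graph.nx.edges(data=True))
        shuffled = SignalingGraph(
            [(u, d["interaction"], v) for u, v, d in reversed(edges)],
            nodes=sorted(graph.nodes, reverse=True),
        )
        nodes = sorted(graph.nodes)
        part = CascadePartition.from_sets(set(nodes[:2]), set(nodes[-3:]), graph)
        net1 = wn.infer_cascades(graph, part)
        net2 = wn.infer_cascades(shuffled, part)
        assert net1.edges == net2.edges
        assert net1.roles == net2.roles

    def test_lexicographic_first_is_subset_of_all(self, diamond_graph):
        part = CascadePartition.from_sets({"A"}, {"D"}, diamond_graph)
        net_all = wn.infer_cascades(diamond_graph, part, tie_policy="all")
        net_one = wn.infer_cascades(diamond_graph, part, tie_policy="lexicographic-first")
        assert net_one.edges == {("A", "B"), ("B", "D")}
        assert net_one.edges <= net_all.edges
        assert net_all.edges == {("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")}

    def test_adding_edge_never_increases_recorded_distances(self):
        """Monotonicity of shortest paths under edge insertion."""
        rng = np.random.default_rng(201)
        graph = random_digraph(rng, 9, 0.15)
        nodes = sorted(graph.nodes)
        part = CascadePartition.from_sets({nodes[0]}, set(nodes[-2:]), graph)
        net1 = wn.infer_cascades(graph, part)
        d1 = {
            (p["source"], p["target"]): p["length"]
            for it in net1.iteration_log
            for p in it["pairs"]
        }
        # add one fresh edge
        candidates = [
            (u, v) for u in nodes for v in nodes
            if u != v and not graph.nx.has_edge(u, v)
        ]
        u, v = candidates[0]
        aug = SignalingGraph(
            list(graph.nx.edges()) + [(u, v)], nodes=nodes
        )
        net2 = wn.infer_cascades(aug, part)
        d2 = {
            (p["source"], p["target"]): p["length"]
            for it in net2.iteration_log
            for p in it["pairs"]
        }
        for pair, length in d1.items():
            if pair in d2:
                assert d2[pair] <= length

    def test_recorded_path_lengths_equal_bfs_distance(self, default_config):
        import networkx as nx

        graph, truth = wn.generate_signaling_graph(default_config)
        part = CascadePartition.from_sets(
            truth.planted_sources, truth.planted_targets, graph
        )
        net = wn.infer_cascades(graph, part)
        for it in net.iteration_log:
            for p in it["pairs"]:
                assert p["length"] == nx.shortest_path_length(
                    graph.nx, p["source"], p["target"]
                )


class TestSummarize:
    def test_counts_and_annotations(self):
        graph = SignalingGraph([("A", "B"), ("B", "C")])
        part = CascadePartition.from_sets({"A"}, {"C"}, graph)
        net = wn.infer_cascades(graph, part)
        table = wn.summarize_network(
            net, wn.GeneSetCollection({"anno1": {"A", "B"}, "anno2": {"Z"}})
        )
        values = dict(zip(table["metric"], table["value"]))
        assert values["n_nodes"] == 3
        assert values["n_edges"] == 2
        assert values["n_source"] == 1 and values["n_linker"] == 1 and values["n_target"] == 1
        assert values["annotation:anno1"] == 2
        assert values["annotation:anno2"] == 0

    def test_annotation_equal_to_nodes(self):
        graph = SignalingGraph([("A", "B")])
        net = wn.infer_cascades(
            graph, CascadePartition.from_sets({"A"}, {"B"}, graph)
        )
        table = wn.summarize_network(net, wn.GeneSetCollection({"all": {"A", "B"}}))
        values = dict(zip(table["metric"], table["value"]))
        assert values["annotation:all"] == values["n_nodes"]

    def test_without_annotations(self):
        graph = SignalingGraph([("A", "B")])
        net = wn.infer_cascades(
            graph, CascadePartition.from_sets({"A"}, {"B"}, graph)
        )
        table = wn.summarize_network(net)
        assert set(table["metric"]) == {
            "n_nodes", "n_edges", "n_unreachable_targets",
            "n_source", "n_linker", "n_target",
        }
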