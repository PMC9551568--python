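import numpy as np
import pandas as pd
import pytest

from weaknet import LabeledExpressionMatrix, SignalingGraph, SimulationConfig


@pytest.fixture
def chain_graph():
    """A -> B -> C."""
    return SignalingGraph([("A", "B"), ("B", "C")])


@pytest.fixture
def diamond_graph():
    """A -> {B, C} -> D (two tied shortest paths A..D)."""
    return SignalingGraph([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])


@pytest.fixture
def toy_matrix():
    """4 genes x 6 samples, 3 control + 3 case, reproducible values."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.lognormal(3.0, 0.8, (4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{j}" for j in range(6)],
    )
    group = {f"s{j}": ("control" if j < 3 else "case") for j in range(6)}
    return LabeledExpressionMatrix(values, group)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


def random_digraph(rng, n_nodes, p_edge):
    """Small random directed graph over letter-named nodes."""
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    edges = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and rng.random() < p_edge
    ]
    return SignalingGraph(edges, nodes=nodes)
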