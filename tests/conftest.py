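import os
import sys

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from gwasnet.score import z_transform
from gwasnet.smooth import WalkParams, WorkingNetwork, edge_weights, random_walk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph():
    """A-B-C path, all p = 0 (maximal edge weights)."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


def make_working_network(graph: nx.Graph, p: dict[str, float],
                         seed_threshold: float = 0.05,
                         params: WalkParams = WalkParams()) -> WorkingNetwork:
    """Build a WorkingNetwork from explicit per-gene p-values."""
    pser = pd.Series(p)
    scores = pd.DataFrame({"p": pser})
    scores["z"] = z_transform(scores["p"].to_numpy())
    seeds = set(scores.index[scores["p"] <= seed_threshold])
    scores["seed"] = scores.index.isin(seeds)
    weighted = edge_weights(graph, scores["p"])
    scores["node_weight"] = random_walk(weighted, seeds, params)
    return WorkingNetwork(graph=weighted, scores=scores.sort_index(), params=params)


@pytest.fixture
def clique_toy():
    """12-node graph: 5-clique with p=1e-6 inside, p=0.9 outside."""
    g = nx.Graph()
    clique = ["C1", "C2", "C3", "C4", "C5"]
    for i, a in enumerate(clique):
        for b in clique[i + 1:]:
            g.add_edge(a, b)
    others = [f"O{i}" for i in range(1, 8)]
    g.add_edges_from([("C1", "O1"), ("O1", "O2"), ("O2", "O3"), ("C3", "O4"),
                      ("O4", "O5"), ("O5", "O6"), ("O6", "O7"), ("O3", "O7")])
    p = {n: 1e-6 for n in clique}
    p.update({n: 0.9 for n in others})
    return g, p, set(clique)
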