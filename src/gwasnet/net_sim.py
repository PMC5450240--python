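"""Synthetic interaction networks with planted signal modules.

Scale-free (preferential-attachment) graphs stand in for real PPI networks,
whose heavy-tailed degree distribution is what stresses column normalization
and the restart walk.  A connected "truth" module of chosen size is planted
by a seeded random walk over the graph (avoiding the degenerate star shapes
a BFS ball would give); genes inside the module draw small p-values, genes
outside draw from a background distribution.  Recovery of the truth set is
summarized by the usual overlap metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PlantSpec",
    "generate_network",
    "plant_module",
    "recovery_metrics",
    "uniform",
    "point_mass",
]


def uniform(lo: float, hi: float) -> Callable:
    """Distribution spec: p ~ Uniform(lo, hi)."""
    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=size)
    return draw


def point_mass(value: float) -> Callable:
    """Distribution spec: p = value always."""
    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, value)
    return draw


@dataclass(frozen=True)
class PlantSpec:
    """How to plant a signal module: its size and the p-value distributions
    inside (planted genes) and outside (background genes)."""

    module_size: int = 30
    p_dist_in: Callable = uniform(0.0, 1e-4)
    p_dist_out: Callable = uniform(0.0, 1.0)
    rng_seed: int | None = None


def generate_network(n_nodes: int, edges_per_node: int = 2,
                     rng_seed: int | None = None) -> nx.Graph:
    """Connected preferential-attachment graph with symbols G0001, G0002, ...

    The attachment scheme adds ``edges_per_node`` edges for each node beyond
    the initial clique-free core, so the edge count is exactly
    ``(n_nodes - edges_per_node) * edges_per_node``.
    """
    if not n_nodes > edges_per_node >= 1:
        raise ValueError(f"need n_nodes > edges_per_node >= 1, got {n_nodes}, {edges_per_node}")
    seed = int(np.random.default_rng(rng_seed).integers(2**31))
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=seed)
    width = max(4, len(str(n_nodes)))
    return nx.relabel_nodes(g, {i: f"G{i + 1:0{width}d}" for i in g.nodes})


def _walk_subgraph(graph: nx.Graph, size: int, rng: np.random.Generator) -> set[str]:
    """Connected node set collected by a random walk restarted from visited nodes."""
    nodes = sorted(graph.nodes)
    for _attempt in range(50):
        current = nodes[rng.integers(len(nodes))]
        visited = {current}
        stall = 0
        while len(visited) < size and stall < 10_000:
            nbrs = list(graph.neighbors(current))
            if not nbrs:
                break
            current = nbrs[rng.integers(len(nbrs))]
            if current in visited:
                stall += 1
            else:
                visited.add(current)
                stall = 0
        if len(visited) == size:
            return visited
    raise RuntimeError(f"could not collect a connected subgraph of size {size}")


def plant_module(graph: nx.Graph, spec: PlantSpec) -> tuple[pd.DataFrame, set[str]]:
    """Assign gene-level p-values with a planted connected signal module.

    Returns ``(scores, truth)``: a DataFrame indexed by gene with column
    ``p``, and the planted gene set.  With ``module_size=0`` no module is
    planted (pure null scores).
    """
    if spec.module_size > graph.number_of_nodes():
        raise ValueError("module_size exceeds network size")
    rng = np.random.default_rng(spec.rng_seed)
    nodes = sorted(graph.nodes)
    truth: set[str] = set()
    if spec.module_size > 0:
        truth = _walk_subgraph(graph, spec.module_size, rng)
    p = pd.Series(spec.p_dist_out(rng, len(nodes)), index=nodes, name="p")
    if truth:
        inside = sorted(truth)
        p.loc[inside] = spec.p_dist_in(rng, len(inside))
    return pd.DataFrame({"p": p}), truth


def recovery_metrics(found, truth) -> dict[str, float]:
    """Jaccard, Dice, precision and recall of a recovered set vs the truth."""
    found, truth = set(found), set(truth)
    if not truth:
        raise ValueError("truth set is empty")
    inter = len(found & truth)
    union = len(found | truth)
    return {
        "jaccard": inter / union if union else 0.0,
        "dice": 2.0 * inter / (len(found) + len(truth)),
        "precision": inter / len(found) if found else 0.0,
        "recall": inter / len(truth),
    }
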