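"""Independent oracles used by several test modules."""

import itertools

import networkx as nx
import numpy as np

from gwasnet.score import BackgroundTable, adjusted_score, network_zscore


def connected_subsets(graph: nx.Graph, max_size: int | None = None):
    """Enumerate every connected node subset of a small graph.

    Standard expansion enumeration: each subset is generated exactly once by
    growing from its smallest node and only ever adding allowed extensions.
    """
    nodes = sorted(graph.nodes)
    order = {n: i for i, n in enumerate(nodes)}
    if max_size is None:
        max_size = len(nodes)

    def expand(current: frozenset, candidates: set, forbidden: set):
        yield current
        if len(current) == max_size:
            return
        cands = sorted(candidates, key=order.get)
        for i, v in enumerate(cands):
            new_forbidden = forbidden | set(cands[:i])
            new_cands = (candidates | set(graph.neighbors(v))) - current - {v} - new_forbidden
            yield from expand(current | {v}, new_cands, new_forbidden)

    for i, root in enumerate(nodes):
        yield from expand(frozenset([root]),
                          set(graph.neighbors(root)) - set(nodes[:i]),
                          set(nodes[:i]))


def brute_force_best(graph, scores, bg: BackgroundTable, max_size: int | None = None):
    """Exhaustive maximum adjusted score over all connected subsets."""
    best_S, best_set = -np.inf, None
    cap = min(max_size or len(graph), bg.k_max)
    for subset in connected_subsets(graph, cap):
        try:
            Z = network_zscore(subset, scores)
        except ValueError:
            continue
        S = adjusted_score(Z, len(subset), bg)
        if S > best_S:
            best_S, best_set = S, subset
    return best_set, best_S
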