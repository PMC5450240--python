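"""Seed selection, p-value edge weighting and random walk with restart.

Gene-level p-values are mapped onto the interaction network; the nominally
significant genes (p <= 0.05 by default) become seeds.  Each edge (i, j) is
weighted by the mean significance of its endpoints,

    W_ij = ((1 - p_i) + (1 - p_j)) / 2,

the weight matrix is normalized by columns, and seed mass is diffused by a
fixed number of synchronous random-walk-with-restart steps

    P(t) = (1 - r) * Wn @ P(t-1) + r * P(0),

with P(0) = 1 on seeds and 0 elsewhere.  P(T) supplies the node weights used
by the subnetwork score.  The walk runs on the subgraph induced by scored
genes only; nodes without a p-value are discarded (and counted in the log),
since edge weights are undefined for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .score import z_transform

log = logging.getLogger(__name__)

__all__ = [
    "WalkParams",
    "WorkingNetwork",
    "select_seeds",
    "edge_weights",
    "column_normalize",
    "random_walk",
    "smooth_scores",
]


@dataclass(frozen=True)
class WalkParams:
    """Random-walk-with-restart parameters: restart ratio and step count."""

    r: float = 0.5
    T: int = 5

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"restart ratio r={self.r} outside [0, 1]")
        if self.T < 0:
            raise ValueError(f"step count T={self.T} must be non-negative")


def select_seeds(scores: pd.DataFrame, threshold: float = 0.05) -> set[str]:
    """Genes with p <= threshold (inclusive).  Raises if none qualify."""
    if scores.empty:
        raise ValueError("empty score table")
    seeds = set(scores.index[scores["p"] <= threshold])
    if not seeds:
        raise ValueError(f"no seed genes at p <= {threshold}; pipeline cannot proceed")
    log.info("select_seeds: %d of %d genes at p <= %g", len(seeds), len(scores), threshold)
    return seeds


def edge_weights(graph: nx.Graph, p: pd.Series) -> nx.Graph:
    """Return a copy of ``graph`` with edge attribute ``weight`` filled in.

    Every node must have a p-value; restrict the graph first if not.
    """
    missing = [n for n in graph.nodes if n not in p.index]
    if missing:
        raise KeyError(
            f"{len(missing)} network genes lack a p-value (e.g. {missing[:3]}); "
            "restrict the network to scored genes first"
        )
    out = graph.copy()
    for i, j in out.edges:
        out[i][j]["weight"] = ((1.0 - p[i]) + (1.0 - p[j])) / 2.0
    return out


def column_normalize(graph: nx.Graph, nodes: list[str] | None = None) -> tuple[list[str], sp.csr_matrix]:
    """Column-normalized walk operator of the weighted adjacency matrix.

    Each non-zero column is divided by its sum; zero columns (isolated nodes)
    are left untouched.  Returns the node ordering and a CSR matrix.
    """
    if nodes is None:
        nodes = sorted(graph.nodes)
    W = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csc")
    colsum = np.asarray(W.sum(axis=0)).ravel()
    scale = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    Wn = W @ sp.diags(scale)
    return nodes, sp.csr_matrix(Wn)


def random_walk(graph: nx.Graph, seeds: set[str], params: WalkParams = WalkParams()) -> pd.Series:
    """Run T restart-walk steps from the seed indicator; returns P(T) per gene.

    P(0) carries 1 on each seed and 0 elsewhere (deliberately unnormalized:
    the downstream weighted-Z score is invariant to uniform rescaling).
    """
    nodes, Wn = column_normalize(graph)
    index = {n: i for i, n in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    for s in seeds:
        if s in index:
            p0[index[s]] = 1.0
    pt = p0.copy()
    for _ in range(params.T):
        pt = (1.0 - params.r) * (Wn @ pt) + params.r * p0
    return pd.Series(pt, index=nodes, name="node_weight")


@dataclass
class WorkingNetwork:
    """The scored, weighted, smoothed network the module search operates on."""

    graph: nx.Graph
    scores: pd.DataFrame  # index gene; columns p, z, seed, node_weight
    params: WalkParams = field(default_factory=WalkParams)


def smooth_scores(graph: nx.Graph, gene_p: pd.Series | pd.DataFrame,
                  seed_threshold: float = 0.05,
                  params: WalkParams = WalkParams()) -> WorkingNetwork:
    """End-to-end smoothing: restrict, seed, weight edges, walk.

    ``gene_p`` maps gene symbols to gene-level p-values (a Series, or a
    DataFrame with a ``p`` column).  Network nodes without a p-value are
    dropped; scored genes absent from the network are ignored.
    """
    if isinstance(gene_p, pd.DataFrame):
        gene_p = gene_p["p"]
    scored = [n for n in graph.nodes if n in gene_p.index]
    dropped = graph.number_of_nodes() - len(scored)
    if dropped:
        log.info("smooth_scores: dropped %d unscored network genes", dropped)
    sub = graph.subgraph(scored).copy()
    p = gene_p.loc[list(sub.nodes)]
    scores = pd.DataFrame({"p": p})
    scores["z"] = z_transform(scores["p"].to_numpy())
    seeds = select_seeds(scores, seed_threshold)
    scores["seed"] = scores.index.isin(seeds)
    weighted = edge_weights(sub, scores["p"])
    scores["node_weight"] = random_walk(weighted, seeds, params)
    scores = scores.sort_index()
    return WorkingNetwork(graph=weighted, scores=scores, params=params)
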