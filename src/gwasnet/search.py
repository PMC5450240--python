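"""Greedy seed-and-grow search for high-scoring connected subnetworks.

Each seed gene starts one growth attempt.  From the current gene set the
adjusted score S of every "current set + one neighboring gene" candidate is
evaluated; the best neighbor is added if it strictly improves S, and growth
stops otherwise (plain hill-climbing) or at the size cap.  Modules passing
the score and size filters are deduplicated and ranked by S.

Run-to-run stochasticity enters through (a) the run-specific background
calibration and (b) the shuffled order of growth starts; everything is
driven by a single per-run seed, so a run is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .score import (BackgroundTable, adjusted_score, calibrate_background,
                    smooth_background)
from .smooth import WalkParams, WorkingNetwork, smooth_scores

log = logging.getLogger(__name__)

__all__ = ["SearchParams", "Subnetwork", "RunResult", "grow_module", "search_run"]


@dataclass(frozen=True)
class SearchParams:
    """Search thresholds: restart/steps of the walk, minimum adjusted score,
    size bounds and the run's random seed."""

    r: float = 0.5
    T: int = 5
    min_score: float = 3.0       # modules kept only when S > min_score
    min_size: int = 5
    max_size: int = 300
    rng_seed: int = 1
    seed_threshold: float = 0.05
    bg_k_max: int = 500
    bg_n_draws: int = 1000
    bg_smooth_window: int = 9

    def walk_params(self) -> WalkParams:
        return WalkParams(r=self.r, T=self.T)


@dataclass(frozen=True)
class Subnetwork:
    """A connected gene set with its raw (Z) and background-adjusted (S) score."""

    genes: frozenset[str]
    start: str
    Z: float
    S: float

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class RunResult:
    """Ranked output of one stochastic search run."""

    rng_seed: int
    subnetworks: list[Subnetwork]
    network: WorkingNetwork | None = None
    background: BackgroundTable | None = None

    @property
    def top(self) -> Subnetwork:
        if not self.subnetworks:
            raise ValueError("run produced no subnetworks")
        return self.subnetworks[0]

    def rescore(self, genes) -> tuple[float, float]:
        """Z and S of an arbitrary gene set under this run's weights/background."""
        from .score import network_zscore

        Z = network_zscore(genes, self.network.scores)
        return Z, adjusted_score(Z, len(list(genes)), self.background)


class _Arrays:
    """Flat per-node arrays + adjacency lists for fast incremental scoring."""

    def __init__(self, wn: WorkingNetwork):
        self.nodes = list(wn.scores.index)
        self.index = {g: i for i, g in enumerate(self.nodes)}
        self.w = wn.scores["node_weight"].to_numpy(dtype=float)
        self.z = wn.scores["z"].to_numpy(dtype=float)
        self.p = wn.scores["p"].to_numpy(dtype=float)
        self.wz = self.w * self.z
        self.w2 = self.w * self.w
        self.adj = {
            self.index[g]: np.fromiter(
                (self.index[n] for n in wn.graph.neighbors(g)), dtype=np.int64
            )
            for g in self.nodes
            if g in wn.graph
        }


def _grow(arr: _Arrays, start_idx: int, bg: BackgroundTable, cap: int) -> tuple[list[int], float, float]:
    """Hill-climb from a singleton; returns (member indices, Z, S)."""
    members = [start_idx]
    in_set = {start_idx}
    num = arr.wz[start_idx]
    den2 = arr.w2[start_idx]
    if den2 == 0.0:
        # a weightless start cannot be scored; report S = -inf so it is filtered
        return members, 0.0, float("-inf")
    S = adjusted_score(num / np.sqrt(den2), 1, bg)
    frontier: set[int] = set(arr.adj.get(start_idx, ()).tolist()) - in_set
    while frontier and len(members) < cap:
        cand = np.fromiter(frontier, dtype=np.int64)
        k_new = len(members) + 1
        num_new = num + arr.wz[cand]
        den_new = np.sqrt(den2 + arr.w2[cand])
        with np.errstate(divide="ignore", invalid="ignore"):
            Z_new = np.where(den_new > 0, num_new / den_new, -np.inf)
        S_new = (Z_new - bg.mu[k_new - 1]) / bg.sigma[k_new - 1]
        best = S_new.max()
        if not best > S:
            break
        # tie-break among equally scoring candidates: smaller gene p, then symbol
        ties = cand[S_new == best]
        if len(ties) > 1:
            order = sorted(ties, key=lambda i: (arr.p[i], arr.nodes[i]))
            pick = order[0]
        else:
            pick = int(ties[0])
        members.append(pick)
        in_set.add(pick)
        num += arr.wz[pick]
        den2 += arr.w2[pick]
        S = float((num / np.sqrt(den2) - bg.mu[len(members) - 1]) / bg.sigma[len(members) - 1])
        frontier.discard(pick)
        frontier.update(i for i in arr.adj.get(pick, ()).tolist() if i not in in_set)
    Z = float(num / np.sqrt(den2)) if den2 > 0 else 0.0
    return members, Z, S


def grow_module(start: str, wn: WorkingNetwork, bg: BackgroundTable,
                params: SearchParams = SearchParams()) -> Subnetwork:
    """Grow one module from ``start`` by greedy hill-climbing on S."""
    if start not in wn.scores.index:
        raise KeyError(f"start gene {start!r} not in the working network")
    arr = _Arrays(wn)
    cap = min(params.max_size, bg.k_max)
    members, Z, S = _grow(arr, arr.index[start], bg, cap)
    return Subnetwork(genes=frozenset(arr.nodes[i] for i in members), start=start, Z=Z, S=S)


def search_run(graph, gene_p, params: SearchParams = SearchParams(),
               background: BackgroundTable | None = None,
               keep_context: bool = True) -> RunResult:
    """One full stochastic search run.

    Smooths the scores, calibrates a run-specific background, grows a module
    from every seed gene in shuffled order, filters by ``S > min_score`` and
    the size bounds, deduplicates identical gene sets (first kept) and ranks
    by S descending.  A run with no seed genes or no passing module returns
    an empty result with a warning rather than failing, so null data can be
    screened in bulk.
    """
    rng = np.random.default_rng(params.rng_seed)
    try:
        wn = smooth_scores(graph, gene_p, params.seed_threshold, params.walk_params())
    except ValueError as err:
        log.warning("search_run(seed=%d): %s", params.rng_seed, err)
        return RunResult(rng_seed=params.rng_seed, subnetworks=[])
    bg = background
    if bg is None:
        bg = calibrate_background(wn.scores, k_max=params.bg_k_max,
                                  n_draws=params.bg_n_draws, rng=rng)
        bg = smooth_background(bg, params.bg_smooth_window)
    arr = _Arrays(wn)
    starts = [g for g in wn.scores.index[wn.scores["seed"]]]
    rng.shuffle(starts)
    cap = min(params.max_size, bg.k_max)
    seen: set[frozenset[str]] = set()
    found: list[Subnetwork] = []
    for start in starts:
        members, Z, S = _grow(arr, arr.index[start], bg, cap)
        if not (S > params.min_score):
            continue
        if not params.min_size <= len(members) <= params.max_size:
            continue
        genes = frozenset(arr.nodes[i] for i in members)
        if genes in seen:
            continue
        seen.add(genes)
        found.append(Subnetwork(genes=genes, start=start, Z=Z, S=S))
    found.sort(key=lambda m: (-m.S, m.size, tuple(sorted(m.genes))))
    if not found:
        log.warning("search_run(seed=%d): no module passed S > %g with size in [%d, %d]",
                    params.rng_seed, params.min_score, params.min_size, params.max_size)
    else:
        log.info("search_run(seed=%d): %d modules, top S=%.3f size=%d",
                 params.rng_seed, len(found), found[0].S, found[0].size)
    return RunResult(rng_seed=params.rng_seed, subnetworks=found,
                     network=wn if keep_context else None,
                     background=bg if keep_context else None)
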