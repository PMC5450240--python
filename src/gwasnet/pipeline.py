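"""End-to-end orchestration: repeated searches, consensus, enrichment.

The four stages mirror a network-based GWAS pathway analysis: (1) SNP-level
association (or directly supplied gene-level p-values), (2) gene-based
testing, (3) repeated stochastic network searches and consensus-module
extraction, (4) pathway enrichment of the consensus results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from .consensus import (ConsensusModule, common_subnetwork, consensus_module,
                        unique_modules)
from .search import RunResult, SearchParams, search_run

log = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "run_searches", "run_consensus", "run_pipeline"]


@dataclass
class ConsensusResult:
    """Everything the consensus stage produces from a set of runs."""

    runs: list[RunResult]
    consensus: list[ConsensusModule]
    unique: list[ConsensusModule]
    common: set[str]


def run_searches(graph: nx.Graph, gene_p: pd.Series | pd.DataFrame,
                 params: SearchParams = SearchParams(),
                 seeds: list[int] | None = None) -> list[RunResult]:
    """One search run per random seed (default seeds 1..10)."""
    seeds = list(seeds) if seeds is not None else list(range(1, 11))
    runs = []
    for s in seeds:
        runs.append(search_run(graph, gene_p, replace(params, rng_seed=s)))
    log.info("run_searches: %d run results", len(runs))
    return runs


def run_consensus(runs: list[RunResult]) -> ConsensusResult:
    """Consensus modules, unique modules and the common subnetwork.

    Runs that produced no subnetwork are skipped (with a warning); at least
    two productive runs are required.
    """
    productive = [r for r in runs if r.subnetworks]
    if len(productive) < len(runs):
        log.warning("run_consensus: %d of %d runs were empty and are skipped",
                    len(runs) - len(productive), len(runs))
    if len(productive) < 2:
        raise ValueError("consensus requires at least 2 productive runs")
    cms = [consensus_module(r.rng_seed, productive) for r in productive]
    uniq = unique_modules([cm for cm in cms if cm.genes])
    common = common_subnetwork(uniq) if uniq else set()
    return ConsensusResult(runs=runs, consensus=cms, unique=uniq, common=common)


def run_pipeline(graph: nx.Graph, gene_p: pd.Series | pd.DataFrame,
                 params: SearchParams = SearchParams(),
                 seeds: list[int] | None = None,
                 library: dict[str, set[str]] | None = None,
                 enrich_n_null: int = 1000) -> dict:
    """Full analysis: searches, consensus, optional enrichment of the common
    subnetwork (and of each unique consensus module) against a GMT library.

    Returns a dict with keys ``runs``, ``consensus``, ``enrichment`` (a
    per-module dict of tables, present only when a library is given).
    """
    runs = run_searches(graph, gene_p, params, seeds)
    result = run_consensus(runs)
    out = {"runs": runs, "consensus": result, "enrichment": None}
    if library is not None:
        from .enrich import enrich_query

        background = {g for g in graph.nodes}
        tables: dict[str, pd.DataFrame] = {}
        for i, cm in enumerate(result.unique, start=1):
            tables[f"CM{i}"] = enrich_query(cm.genes, library, background,
                                            n_null=enrich_n_null, rng=params.rng_seed)
        if result.common:
            tables["common"] = enrich_query(result.common, library, background,
                                            n_null=enrich_n_null, rng=params.rng_seed)
        out["enrichment"] = tables
    return out
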