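"""Consensus modules across repeated stochastic search runs.

The top subnetwork TN_a of each run a is matched to its most Dice-similar
subnetwork SN_b in every other run b; the consensus module of run a is the
intersection

    CM_a = TN_a  ∩  (∩_{b != a} SN_b(TN_a)).

Identical consensus modules from different runs collapse to unique CMs, and
the intersection of all unique CMs is the common subnetwork — the genes that
every stochastic run agrees on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .search import RunResult, Subnetwork

log = logging.getLogger(__name__)

__all__ = [
    "ConsensusModule",
    "dice",
    "most_similar",
    "consensus_module",
    "unique_modules",
    "common_subnetwork",
]


def dice(m, n) -> float:
    """Dice set-similarity coefficient ``2|m ∩ n| / (|m| + |n|)``."""
    m, n = set(m), set(n)
    if not m and not n:
        raise ValueError("Dice coefficient undefined for two empty sets")
    return 2.0 * len(m & n) / (len(m) + len(n))


def most_similar(tn: Subnetwork, run_b: RunResult) -> tuple[Subnetwork, int, float]:
    """The subnetwork of ``run_b`` maximizing Dice similarity to ``tn``.

    Returns (subnetwork, 1-based rank within run_b, Dice value).  Ties are
    broken in favor of the better-ranked (higher-S) subnetwork; run_b is
    already rank-ordered, so the first maximum wins.
    """
    if not run_b.subnetworks:
        raise ValueError(f"run {run_b.rng_seed} has no subnetworks to match against")
    best_rank, best_dc = 0, -1.0
    for rank, sn in enumerate(run_b.subnetworks, start=1):
        dc = dice(tn.genes, sn.genes)
        if dc > best_dc:
            best_rank, best_dc = rank, dc
    return run_b.subnetworks[best_rank - 1], best_rank, best_dc


@dataclass
class ConsensusModule:
    """Intersection of one run's top subnetwork with its best matches elsewhere."""

    genes: frozenset[str]
    source_run: int
    matched: dict[int, tuple[int, float]]  # other run seed -> (rank of SN_b, DC)
    Z: float = float("nan")
    S: float = float("nan")
    source_runs: list[int] = field(default_factory=list)  # filled by unique_modules

    @property
    def size(self) -> int:
        return len(self.genes)


def consensus_module(a: int, runs: list[RunResult]) -> ConsensusModule:
    """Consensus module seeded by run ``a`` (its rng seed) over all runs.

    Z and S of the final intersection are recomputed under run a's node
    weights and background when that context is attached to the run.
    An empty intersection yields an empty module with a warning.
    """
    if len(runs) < 2:
        raise ValueError("consensus requires at least 2 runs")
    by_seed = {r.rng_seed: r for r in runs}
    run_a = by_seed[a]
    tn = run_a.top
    genes = set(tn.genes)
    matched: dict[int, tuple[int, float]] = {}
    for r in runs:
        if r.rng_seed == a:
            continue
        sn, rank, dc = most_similar(tn, r)
        matched[r.rng_seed] = (rank, dc)
        genes &= sn.genes
    if not genes:
        log.warning("consensus_module(run %d): empty intersection", a)
        return ConsensusModule(genes=frozenset(), source_run=a, matched=matched)
    cm = ConsensusModule(genes=frozenset(genes), source_run=a, matched=matched)
    if run_a.network is not None and run_a.background is not None:
        cm.Z, cm.S = run_a.rescore(genes)
    return cm


def unique_modules(cms: list[ConsensusModule]) -> list[ConsensusModule]:
    """Merge consensus modules with identical gene sets, keeping provenance.

    The first occurrence is kept; its ``source_runs`` accumulates the seeds
    of every run that produced the same gene set.
    """
    seen: dict[frozenset[str], ConsensusModule] = {}
    out: list[ConsensusModule] = []
    for cm in cms:
        if cm.genes in seen:
            seen[cm.genes].source_runs.append(cm.source_run)
        else:
            cm.source_runs = [cm.source_run]
            seen[cm.genes] = cm
            out.append(cm)
    log.info("unique_modules: %d consensus modules -> %d unique", len(cms), len(out))
    return out


def common_subnetwork(cms: list[ConsensusModule]) -> set[str]:
    """Genes shared by every (unique) consensus module."""
    if not cms:
        raise ValueError("no consensus modules given")
    genes = set(cms[0].genes)
    for cm in cms[1:]:
        genes &= cm.genes
    if not genes:
        log.warning("common_subnetwork: empty intersection")
    return genes
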