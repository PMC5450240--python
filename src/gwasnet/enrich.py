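"""Pathway enrichment of module gene sets.

For a query gene set against a GMT library the table carries, per pathway:
the one-sided Fisher exact (hypergeometric upper-tail) p-value of the
overlap, its Benjamini–Hochberg adjustment, a z-score measuring how far the
pathway's rank in the library deviates from its rank distribution under
random queries of the same size (negative = better than expected), and the
combined score c = ln(p_adj) * z, which is positive for pathways that are
both significant and better-ranked than chance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "fisher_enrich",
    "bh_adjust",
    "rank_zscore",
    "combined_score",
    "enrich_query",
]

_P_FLOOR = 1e-300


def fisher_enrich(query, pathway, background) -> tuple[float, set[str]]:
    """One-sided Fisher exact p of the query/pathway overlap.

    Genes outside the background are dropped with a warning.  Returns
    ``(p, overlap gene set)`` where p = P(X >= observed overlap) for
    X ~ Hypergeom(N=|background|, K=|pathway|, n=|query|).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene universe")
    q = set(query) & background
    pw = set(pathway) & background
    if len(q) < len(set(query)) or len(pw) < len(set(pathway)):
        log.warning("fisher_enrich: %d query / %d pathway genes outside background dropped",
                    len(set(query)) - len(q), len(set(pathway)) - len(pw))
    overlap = q & pw
    p = float(stats.hypergeom.sf(len(overlap) - 1, len(background), len(pw), len(q)))
    return min(p, 1.0), overlap


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def _library_pvals(query_mask: np.ndarray, pw_mask: np.ndarray, n_bg: int) -> np.ndarray:
    """Vector of hypergeometric upper-tail p-values over all pathways.

    ``query_mask`` is a boolean background-gene indicator; ``pw_mask`` is the
    pathways x genes membership matrix.
    """
    overlaps = pw_mask @ query_mask
    sizes = pw_mask.sum(axis=1)
    return stats.hypergeom.sf(overlaps - 1, n_bg, sizes, int(query_mask.sum()))


def rank_zscore(query, library: dict[str, set[str]], background,
                n_null: int = 1000,
                rng: np.random.Generator | int | None = None) -> pd.Series:
    """Rank-deviation z-score per pathway.

    The observed rank of each pathway's Fisher p within the library is
    compared with its rank distribution under ``n_null`` uniformly random
    query sets of the same size; z = (observed - mean) / sd.  Pathways with
    a degenerate null rank (sd = 0) get z = 0.
    """
    if len(library) < 2:
        raise ValueError("rank z-score needs a library of at least 2 pathways")
    rng = np.random.default_rng(rng)
    bg = sorted(set(background))
    idx = {g: i for i, g in enumerate(bg)}
    names = list(library)
    pw_mask = np.zeros((len(names), len(bg)), dtype=float)
    for r, name in enumerate(names):
        for g in library[name]:
            if g in idx:
                pw_mask[r, idx[g]] = 1.0
    q = [g for g in set(query) if g in idx]
    q_mask = np.zeros(len(bg))
    q_mask[[idx[g] for g in q]] = 1.0
    obs_rank = stats.rankdata(_library_pvals(q_mask, pw_mask, len(bg)), method="average")
    null_ranks = np.empty((n_null, len(names)))
    for i in range(n_null):
        mask = np.zeros(len(bg))
        mask[rng.choice(len(bg), size=len(q), replace=False)] = 1.0
        null_ranks[i] = stats.rankdata(_library_pvals(mask, pw_mask, len(bg)),
                                       method="average")
    mean = null_ranks.mean(axis=0)
    sd = null_ranks.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs_rank - mean) / sd, 0.0)
    return pd.Series(z, index=names, name="z")


def combined_score(p_adj: float, z: float) -> float:
    """Combined enrichment score ``c = ln(p_adj) * z`` (natural log).

    With z < 0 for better-than-expected ranks, smaller adjusted p and more
    negative z both push c upward.  ``p_adj`` must be positive (clamp
    upstream); values are floored at 1e-300 before the log.
    """
    if p_adj <= 0:
        raise ValueError("adjusted p must be positive; clamp before combining")
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(np.log(max(p_adj, _P_FLOOR)) * z)


def enrich_query(query, library: dict[str, set[str]], background,
                 n_null: int = 1000,
                 rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Full enrichment table for one query gene set, sorted by Fisher p.

    Columns: pathway, overlap (``k/K``), overlap_count, pathway_size,
    query_size, p, p_adj, z, combined, genes (semicolon-joined overlap).
    """
    background = set(background)
    q = set(query) & background
    rows = []
    for name, genes in library.items():
        p, overlap = fisher_enrich(q, genes, background)
        rows.append({
            "pathway": name,
            "overlap_count": len(overlap),
            "pathway_size": len(set(genes) & background),
            "query_size": len(q),
            "p": p,
            "genes": ";".join(sorted(overlap)),
        })
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    zs = rank_zscore(q, library, background, n_null=n_null, rng=rng)
    df["z"] = df["pathway"].map(zs)
    df["combined"] = [
        combined_score(max(pa, _P_FLOOR), z) for pa, z in zip(df["p_adj"], df["z"])
    ]
    df["overlap"] = df["overlap_count"].astype(str) + "/" + df["pathway_size"].astype(str)
    df = df.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    return df[["pathway", "overlap", "overlap_count", "pathway_size", "query_size",
               "p", "p_adj", "z", "combined", "genes"]]
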