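"""Weighted-Z (Liptak–Stouffer) subnetwork scoring with a random-set background.

A gene set ``A`` with per-gene probit scores ``z_i`` and smoothed node
weights ``w_i`` receives the raw score

    Z_A = sum_i w_i * z_i / sqrt(sum_i w_i^2)

which, with equal weights, reduces to the classical Stouffer combination
``sum z / sqrt(k)``.  Because Z_A drifts with set size and with the weight
distribution, it is standardized against an empirical background: for every
size ``k`` the mean and standard deviation of Z over uniformly sampled gene
sets of that size give the adjusted score

    S_A = (Z_A - mu_k) / sigma_k.

Background sets are sampled without any connectivity constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BackgroundTable",
    "z_transform",
    "network_zscore",
    "calibrate_background",
    "smooth_background",
    "adjusted_score",
]

_P_CLAMP = 1e-15


def z_transform(p):
    """Probit score of a p-value: ``z = Phi^{-1}(1 - p)``.

    Smaller p gives larger z (one-sided significance convention); p is
    clamped to ``[1e-15, 1 - 1e-15]`` so the result is always finite.
    Accepts scalars or arrays.
    """
    p = np.clip(np.asarray(p, dtype=float), _P_CLAMP, 1.0 - _P_CLAMP)
    z = stats.norm.isf(p)
    return float(z) if z.ndim == 0 else z


@dataclass(frozen=True)
class BackgroundTable:
    """Null mean/s.d. of Z for uniformly random gene sets of size 1..k_max."""

    mu: np.ndarray
    sigma: np.ndarray
    n_draws: int

    @property
    def k_max(self) -> int:
        return len(self.mu)


def network_zscore(genes, scores: pd.DataFrame) -> float:
    """Raw weighted-Z score of a gene set.

    ``scores`` must be indexed by gene with columns ``z`` and ``node_weight``;
    every gene of the set must be present.  Raises ``ValueError`` when all
    node weights of the set are zero (the statistic is undefined).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("cannot score an empty gene set")
    sub = scores.loc[genes]
    w = sub["node_weight"].to_numpy(dtype=float)
    z = sub["z"].to_numpy(dtype=float)
    denom = np.sqrt(np.sum(w * w))
    if denom == 0.0:
        raise ValueError("all node weights are zero; Z is undefined")
    return float(np.sum(w * z) / denom)


def calibrate_background(scores: pd.DataFrame, k_max: int = 500,
                         n_draws: int = 1000,
                         rng: np.random.Generator | int | None = None) -> BackgroundTable:
    """Estimate mu_k and sigma_k of Z over random gene sets for k = 1..k_max.

    For each size the same number of uniform subsets (without replacement,
    no connectivity requirement) is drawn from the working gene universe.
    The draw is fully vectorized; the table costs O(k_max * n_draws) memory
    transiently.
    """
    rng = np.random.default_rng(rng)
    w = scores["node_weight"].to_numpy(dtype=float)
    z = scores["z"].to_numpy(dtype=float)
    n = len(w)
    if n < k_max:
        raise ValueError(f"network has {n} scored genes; k_max={k_max} is too large")
    wz = w * z
    w2 = w * w
    mu = np.empty(k_max)
    sigma = np.empty(k_max)
    for k in range(1, k_max + 1):
        # first k columns of row-wise random permutations = uniform k-subsets
        idx = np.argpartition(rng.random((n_draws, n)), k - 1, axis=1)[:, :k]
        num = wz[idx].sum(axis=1)
        den = np.sqrt(w2[idx].sum(axis=1))
        if np.any(den == 0.0):
            raise ValueError(
                f"background draw of size {k} hit an all-zero-weight set; "
                "node weights are degenerate"
            )
        zs = num / den
        mu[k - 1] = zs.mean()
        sigma[k - 1] = zs.std(ddof=1)
    if np.any(sigma <= 0.0):
        k_bad = int(np.argmax(sigma <= 0.0)) + 1
        raise ValueError(
            f"degenerate background at k={k_bad}: sigma=0 (identical scores?)"
        )
    return BackgroundTable(mu=mu, sigma=sigma, n_draws=n_draws)


def smooth_background(bg: BackgroundTable, window: int = 9) -> BackgroundTable:
    """Moving-average smoothing of mu_k and sigma_k over k (edge-padded).

    Both curves vary slowly and smoothly in k, so at moderate draw counts
    most of their k-to-k jitter is Monte-Carlo noise; left unsmoothed, that
    jitter leaks into the adjusted score and makes S non-monotone along
    otherwise clean growth trajectories.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1 or bg.k_max < window:
        return bg
    pad = window // 2
    kernel = np.ones(window) / window

    def ma(x):
        return np.convolve(np.pad(x, (pad, pad), mode="edge"), kernel, mode="valid")

    return BackgroundTable(mu=ma(bg.mu), sigma=ma(bg.sigma), n_draws=bg.n_draws)


def adjusted_score(Z: float, k: int, bg: BackgroundTable) -> float:
    """Standardize a raw score against the size-k background: (Z - mu_k)/sigma_k."""
    if not 1 <= k <= bg.k_max:
        raise ValueError(
            f"set size {k} outside calibrated range 1..{bg.k_max}; "
            "recalibrate the background with a larger k_max"
        )
    return float((Z - bg.mu[k - 1]) / bg.sigma[k - 1])
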