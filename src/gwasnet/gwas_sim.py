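"""Synthetic genotypes, phenotypes, QC filtering and per-SNP regression.

The generator emulates the data a quantitative-trait GWAS consumes: LD-blocked
biallelic dosages, a quantitative phenotype with an additive genetic model
plus covariates (an age-like continuous variable, a sex-like binary one and a
multi-level diagnosis factor entered as dummy indicators), standard per-SNP
quality control (call rate, minor allele frequency, Hardy–Weinberg
equilibrium), and ordinary-least-squares association of the trait on each
SNP's dosage with covariate adjustment.

Genotypes within a block are produced by thresholding two AR(1)-correlated
latent Gaussian haplotypes at the MAF quantile, so adjacent SNPs are
correlated (approximately by the latent rho) while Hardy–Weinberg proportions
hold marginally; blocks are mutually independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "QcParams",
    "simulate_genotypes",
    "simulate_phenotype",
    "qc_filter",
    "hwe_chi2_p",
    "snp_association",
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs, NaN = missing) plus SNP metadata."""

    dosages: np.ndarray                    # float array, values {0,1,2,NaN}
    snps: pd.DataFrame                     # columns: snp, chrom, pos, block

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def columns(self, snp_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.snps["snp"])}
        return self.dosages[:, [pos[s] for s in snp_ids]]


@dataclass
class PhenotypeVector:
    """Quantitative trait values with the covariate design used to make them."""

    y: np.ndarray
    covariates: pd.DataFrame   # age-like, sex-like, diagnosis dummies


@dataclass(frozen=True)
class QcParams:
    """Per-SNP exclusion thresholds (all fractions/probabilities in [0, 1])."""

    call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6

    def __post_init__(self):
        for name in ("call_rate_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def simulate_genotypes(n_ind: int, block_spec, rng_seed: int | None = None,
                       missing_rate: float = 0.0, chrom: str = "1") -> GenotypeMatrix:
    """LD-blocked dosages for ``n_ind`` individuals.

    ``block_spec`` is a list of ``(n_snps, ld_rho, (maf_lo, maf_hi))`` tuples;
    each block gets an independent AR(1) latent process with parameter
    ``ld_rho`` and per-SNP minor allele frequencies drawn uniformly from the
    given range.  ``missing_rate`` masks dosages at random.
    """
    if n_ind < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(rng_seed)
    cols, meta = [], []
    pos = 0
    for block_id, (m, rho, maf_range) in enumerate(block_spec):
        lo, hi = maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {maf_range} outside (0, 0.5]")
        if not 0.0 <= rho < 1.0:
            raise ValueError(f"ld_rho={rho} outside [0, 1)")
        mafs = rng.uniform(lo, hi, size=m)
        thresholds = stats.norm.ppf(mafs)
        dos = np.zeros((n_ind, m))
        for _hap in range(2):                      # two independent haplotypes
            latent = np.empty((n_ind, m))
            latent[:, 0] = rng.standard_normal(n_ind)
            scale = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                latent[:, j] = rho * latent[:, j - 1] + scale * rng.standard_normal(n_ind)
            dos += latent < thresholds             # minor allele when below quantile
        cols.append(dos)
        for j in range(m):
            pos += 1000
            meta.append({"snp": f"rs{block_id:03d}_{j:04d}", "chrom": chrom,
                         "pos": pos, "block": block_id})
    dosages = np.concatenate(cols, axis=1)
    if missing_rate > 0.0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan
    return GenotypeMatrix(dosages=dosages, snps=pd.DataFrame(meta))


def simulate_phenotype(G: GenotypeMatrix, causal: dict[str, float],
                       covariate_betas: dict[str, float] | None = None,
                       noise_sd: float = 1.0,
                       rng_seed: int | None = None,
                       n_dx_levels: int = 5) -> PhenotypeVector:
    """Additive quantitative trait: y = sum beta * dosage + covariates + noise.

    ``causal`` maps SNP ids (which must exist in G) to effect sizes.
    ``covariate_betas`` may set effects for ``age``, ``sex`` and ``dx``
    (the latter applied to each non-reference diagnosis dummy, scaled by its
    level index).  Missing dosages contribute their SNP mean.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    known = set(G.snps["snp"])
    unknown = set(causal) - known
    if unknown:
        raise KeyError(f"causal SNPs not in genotype matrix: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(rng_seed)
    n = G.n_individuals
    age = rng.normal(72.0, 7.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    dx = rng.integers(0, n_dx_levels, size=n)
    cov = pd.DataFrame({"age": age, "sex": sex})
    for level in range(1, n_dx_levels):            # reference level dropped
        cov[f"dx{level}"] = (dx == level).astype(float)
    y = np.zeros(n)
    if causal:
        dos = G.columns(list(causal))
        col_mean = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), col_mean, dos)
        y += dos @ np.array(list(causal.values()))
    betas = covariate_betas or {}
    y += betas.get("age", 0.0) * age + betas.get("sex", 0.0) * sex
    if "dx" in betas:
        for level in range(1, n_dx_levels):
            y += betas["dx"] * level * cov[f"dx{level}"].to_numpy()
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=n)
    return PhenotypeVector(y=y, covariates=cov)


def hwe_chi2_p(n0: int, n1: int, n2: int) -> float:
    """1-df chi-square Hardy–Weinberg test p-value from genotype counts.

    ``n0/n1/n2`` are counts of 0, 1 and 2 copies of the minor allele.
    Monomorphic SNPs (allele frequency 0 or 1) return p = 1.
    """
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    q = (2 * n2 + n1) / (2 * n)
    if q in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q * q])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(G: GenotypeMatrix, params: QcParams = QcParams()) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs failing call rate, MAF or Hardy–Weinberg thresholds.

    Returns the filtered matrix and an exclusion report with one row per
    dropped SNP (columns ``snp``, ``reason``, ``value``).  Filters are
    applied in order; a SNP is reported under the first filter it fails.
    """
    keep = []
    report = []
    for j, snp in enumerate(G.snps["snp"]):
        col = G.dosages[:, j]
        present = ~np.isnan(col)
        call_rate = present.mean()
        if call_rate < params.call_rate_min:
            report.append({"snp": snp, "reason": "call_rate", "value": call_rate})
            continue
        obs = col[present]
        af = obs.mean() / 2.0
        maf = min(af, 1.0 - af)
        if maf < params.maf_min:
            report.append({"snp": snp, "reason": "maf", "value": maf})
            continue
        counts = [int(np.sum(obs == g)) for g in (0, 1, 2)]
        p_hwe = hwe_chi2_p(*counts)
        if p_hwe < params.hwe_p_min:
            report.append({"snp": snp, "reason": "hwe", "value": p_hwe})
            continue
        keep.append(j)
    if not keep:
        log.warning("qc_filter: no SNPs survived QC")
    report_df = pd.DataFrame(report, columns=["snp", "reason", "value"])
    out = GenotypeMatrix(dosages=G.dosages[:, keep],
                         snps=G.snps.iloc[keep].reset_index(drop=True))
    log.info("qc_filter: %d of %d SNPs retained (%d excluded)",
             out.n_snps, G.n_snps, len(report_df))
    return out, report_df


def snp_association(G: GenotypeMatrix, y: np.ndarray,
                    covariates: pd.DataFrame | None = None,
                    drop_missing: bool = False) -> pd.DataFrame:
    """Per-SNP ordinary least squares of the trait on dosage + covariates.

    Missing dosages are mean-imputed per SNP by default (``drop_missing=True``
    instead drops the affected individuals for that SNP).  Returns a table
    with columns snp, chrom, pos, beta, se, p, constant (flag for
    zero-variance dosage columns, recorded with p = 1).

    The fit uses the Frisch–Waugh partialling identity: the trait and each
    dosage column are residualized on the covariate design (with intercept),
    and the dosage coefficient's two-sided t-test uses n - p - 1 residual
    degrees of freedom, identical to the full joint OLS.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    n = len(y)
    X = np.ones((n, 1))
    if covariates is not None and len(covariates.columns):
        C = covariates.to_numpy(dtype=float)
        X = np.concatenate([X, C], axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank-deficient")
    Q, _ = np.linalg.qr(X)

    def residualize(v):
        return v - Q @ (Q.T @ v)

    y_res = residualize(y)
    dfree = n - X.shape[1] - 1
    rows = []
    for j in range(G.n_snps):
        col = G.dosages[:, j].copy()
        nan = np.isnan(col)
        snp_meta = G.snps.iloc[j]
        if drop_missing and nan.any():
            use = ~nan
            beta, se, p, const = _ols_single(y[use], col[use], covariates, use)
        else:
            if nan.any():
                col[nan] = np.nanmean(col)
            g_res = residualize(col)
            ss = float(g_res @ g_res)
            if ss <= 1e-12 or np.nanstd(col) == 0.0:
                beta, se, p, const = 0.0, np.nan, 1.0, True
            else:
                beta = float(g_res @ y_res) / ss
                rss = float(y_res @ y_res) - beta * float(g_res @ y_res)
                sigma2 = max(rss, 0.0) / dfree
                se = float(np.sqrt(sigma2 / ss))
                t = beta / se if se > 0 else np.inf
                p = float(2.0 * stats.t.sf(abs(t), dfree)) if np.isfinite(t) else 0.0
                const = False
        rows.append({"snp": snp_meta["snp"], "chrom": snp_meta["chrom"],
                     "pos": int(snp_meta["pos"]), "beta": beta, "se": se,
                     "p": p, "constant": const})
    return pd.DataFrame(rows)


def _ols_single(y, g, covariates, use):
    """Single-SNP OLS on the complete-case subsample (drop-missing mode)."""
    n = len(y)
    X = np.ones((n, 1))
    if covariates is not None and len(covariates.columns):
        X = np.concatenate([X, covariates.to_numpy(dtype=float)[use]], axis=1)
    if g.std() == 0.0:
        return 0.0, np.nan, 1.0, True
    Xf = np.concatenate([X, g[:, None]], axis=1)
    beta_all, _, rank, _ = np.linalg.lstsq(Xf, y, rcond=None)
    resid = y - Xf @ beta_all
    dfree = n - Xf.shape[1]
    sigma2 = float(resid @ resid) / dfree
    XtX_inv = np.linalg.pinv(Xf.T @ Xf)
    se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
    t = beta_all[-1] / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), dfree)) if np.isfinite(t) else 0.0
    return float(beta_all[-1]), se, p, False
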