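import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwasnet.gwas_sim import (GenotypeMatrix, QcParams, hwe_chi2_p, qc_filter,
                              simulate_genotypes, simulate_phenotype,
                              snp_association)


class TestSimulateGenotypes:
    def test_no_ld_gives_near_independent_snps(self):
        G = simulate_genotypes(2000, [(8, 0.0, (0.2, 0.4))], rng_seed=1)
        R = np.corrcoef(G.dosages, rowvar=False)
        off = np.abs(R[~np.eye(8, dtype=bool)])
        assert off.mean() < 0.05

    def test_ld_blocks_are_correlated_within_not_across(self):
        G = simulate_genotypes(3000, [(5, 0.9, (0.3, 0.4)), (5, 0.9, (0.3, 0.4))],
                               rng_seed=2)
        R = np.corrcoef(G.dosages, rowvar=False)
        within = np.mean([R[i, i + 1] for i in (0, 1, 2, 3, 5, 6, 7, 8)])
        across = np.abs(R[:5, 5:]).mean()
        assert within > 0.6        # thresholded AR(1) attenuates the latent rho
        assert across < 0.1

    def test_hardy_weinberg_mean_dosage(self):
        G = simulate_genotypes(10_000, [(1, 0.0, (0.5, 0.5))], rng_seed=3)
        assert np.nanmean(G.dosages) == pytest.approx(1.0, abs=0.05)

    def test_same_seed_identical(self):
        a = simulate_genotypes(50, [(10, 0.5, (0.1, 0.5))], rng_seed=7)
        b = simulate_genotypes(50, [(10, 0.5, (0.1, 0.5))], rng_seed=7)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_invalid_maf_range(self):
        with pytest.raises(ValueError, match="maf_range"):
            simulate_genotypes(10, [(2, 0.0, (0.0, 0.6))], rng_seed=1)

    def test_dosages_in_support(self):
        G = simulate_genotypes(100, [(5, 0.3, (0.1, 0.5))], rng_seed=4,
                               missing_rate=0.1)
        vals = G.dosages[~np.isnan(G.dosages)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}
        assert np.isnan(G.dosages).any()


class TestSimulatePhenotype:
    def test_noiseless_single_causal_is_linear_in_dosage(self):
        G = simulate_genotypes(200, [(3, 0.0, (0.3, 0.5))], rng_seed=5)
        snp = G.snps["snp"][1]
        ph = simulate_phenotype(G, {snp: 2.5}, covariate_betas=None,
                                noise_sd=0.0, rng_seed=5)
        np.testing.assert_allclose(ph.y, 2.5 * G.dosages[:, 1], atol=1e-12)

    def test_unknown_causal_snp_rejected(self):
        G = simulate_genotypes(20, [(2, 0.0, (0.3, 0.5))], rng_seed=6)
        with pytest.raises(KeyError):
            simulate_phenotype(G, {"rsNOPE": 1.0})

    def test_negative_noise_rejected(self):
        G = simulate_genotypes(20, [(2, 0.0, (0.3, 0.5))], rng_seed=6)
        with pytest.raises(ValueError):
            simulate_phenotype(G, {}, noise_sd=-1.0)

    def test_covariate_design_full_rank(self):
        G = simulate_genotypes(300, [(2, 0.0, (0.3, 0.5))], rng_seed=8)
        ph = simulate_phenotype(G, {}, rng_seed=8)
        X = np.column_stack([np.ones(300), ph.covariates.to_numpy()])
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_strong_effect_detected(self):
        G = simulate_genotypes(1000, [(5, 0.0, (0.3, 0.5))], rng_seed=9)
        snp = G.snps["snp"][2]
        var_g = np.var(G.dosages[:, 2])
        beta = np.sqrt(var_g)  # beta^2 var_g = var_g -> R^2 = 0.5 at noise_sd=1
        ph = simulate_phenotype(G, {snp: beta}, noise_sd=1.0, rng_seed=9)
        assoc = snp_association(G, ph.y, ph.covariates)
        assert assoc.set_index("snp").loc[snp, "p"] < 1e-10


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_chi2_p(25, 50, 25) == pytest.approx(1.0)

    def test_excess_heterozygosity_detected(self):
        assert hwe_chi2_p(0, 100, 0) < 1e-6

    def test_monomorphic_returns_one(self):
        assert hwe_chi2_p(100, 0, 0) == 1.0


class TestQcFilter:
    def make(self, dosages):
        dosages = np.asarray(dosages, dtype=float)
        meta = pd.DataFrame({"snp": [f"s{i}" for i in range(dosages.shape[1])],
                             "chrom": "1", "pos": np.arange(dosages.shape[1]),
                             "block": 0})
        return GenotypeMatrix(dosages=dosages, snps=meta)

    def test_low_call_rate_excluded(self):
        col = np.ones((20, 1))
        col[:2] = np.nan  # 10% missing
        G = self.make(np.hstack([col, np.tile([[0.], [1.], [2.], [1.]], (5, 1))]))
        _, report = qc_filter(G, QcParams(call_rate_min=0.95, maf_min=0.0,
                                          hwe_p_min=0.0))
        assert list(report["snp"]) == ["s0"]
        assert report.iloc[0]["reason"] == "call_rate"

    def test_hw_exact_proportions_retained(self):
        col = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=float)[:, None]
        G = self.make(col)
        out, report = qc_filter(G, QcParams(call_rate_min=0.0, maf_min=0.0,
                                            hwe_p_min=1e-6))
        assert out.n_snps == 1 and report.empty

    def test_rare_variant_excluded_by_direct_count(self):
        # 7 minor alleles out of 200 -> MAF 0.035 < 0.05
        col = np.zeros(100)
        col[:7] = 1.0
        G = self.make(col[:, None])
        assert np.nansum(col) / 200 == 0.035
        _, report = qc_filter(G, QcParams(call_rate_min=0.0, maf_min=0.05,
                                          hwe_p_min=0.0))
        assert report.iloc[0]["reason"] == "maf"

    def test_counts_conserved(self):
        G = simulate_genotypes(200, [(30, 0.2, (0.01, 0.5))], rng_seed=11,
                               missing_rate=0.03)
        out, report = qc_filter(G)
        assert out.n_snps + len(report) == G.n_snps


class TestSnpAssociation:
    def test_perfect_fit_underflows(self):
        G = simulate_genotypes(100, [(1, 0.0, (0.4, 0.5))], rng_seed=12)
        y = G.dosages[:, 0].copy()
        assoc = snp_association(G, y)
        assert assoc["p"][0] < 1e-12

    def test_type_one_error_calibrated(self, rng):
        G = simulate_genotypes(1000, [(200, 0.0, (0.1, 0.5))], rng_seed=13)
        y = rng.normal(size=1000)
        assoc = snp_association(G, y)
        frac = (assoc["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.03)

    def test_deterministic_given_inputs(self):
        G = simulate_genotypes(150, [(20, 0.3, (0.2, 0.5))], rng_seed=14)
        ph = simulate_phenotype(G, {}, rng_seed=14)
        a1 = snp_association(G, ph.y, ph.covariates)
        a2 = snp_association(G, ph.y, ph.covariates)
        pd.testing.assert_frame_equal(a1, a2)

    def test_constant_dosage_flagged_with_p_one(self):
        meta = pd.DataFrame({"snp": ["s0"], "chrom": "1", "pos": [1], "block": 0})
        G = GenotypeMatrix(dosages=np.full((30, 1), 2.0), snps=meta)
        assoc = snp_association(G, np.random.default_rng(0).normal(size=30))
        assert assoc["p"][0] == 1.0 and bool(assoc["constant"][0])

    def test_missing_phenotype_rejected(self):
        G = simulate_genotypes(10, [(2, 0.0, (0.3, 0.5))], rng_seed=15)
        y = np.ones(10)
        y[0] = np.nan
        with pytest.raises(ValueError):
            snp_association(G, y)

    def test_drop_missing_mode_close_to_imputation(self):
        G = simulate_genotypes(500, [(5, 0.0, (0.3, 0.5))], rng_seed=16,
                               missing_rate=0.02)
        ph = simulate_phenotype(G, {}, rng_seed=16)
        a_imp = snp_association(G, ph.y, ph.covariates)
        a_drop = snp_association(G, ph.y, ph.covariates, drop_missing=True)
        np.testing.assert_allclose(a_imp["p"], a_drop["p"], atol=0.15)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        G = simulate_genotypes(120, [(4, 0.2, (0.2, 0.5))], rng_seed=17)
        ph = simulate_phenotype(G, {}, rng_seed=17)
        assoc = snp_association(G, ph.y, ph.covariates)
        X0 = sm.add_constant(ph.covariates.to_numpy())
        for j in range(4):
            X = np.column_stack([X0, G.dosages[:, j]])
            fit = sm.OLS(ph.y, X).fit()
            assert assoc["p"][j] == pytest.approx(fit.pvalues[-1], rel=1e-8)
            assert assoc["beta"][j] == pytest.approx(fit.params[-1], rel=1e-8)
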