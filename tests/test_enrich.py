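import itertools
import math

import numpy as np
import pytest

from gwasnet.enrich import (bh_adjust, combined_score, enrich_query,
                            fisher_enrich, rank_zscore)


def hypergeom_tail_by_enumeration(n_bg, k_pathway, n_query, overlap):
    """P(X >= overlap) by direct enumeration of the hypergeometric pmf."""
    total = math.comb(n_bg, n_query)
    return sum(
        math.comb(k_pathway, x) * math.comb(n_bg - k_pathway, n_query - x)
        for x in range(overlap, min(k_pathway, n_query) + 1)
    ) / total


class TestFisherEnrich:
    def test_zero_overlap_gives_p_one(self):
        bg = {f"G{i}" for i in range(10)}
        p, ov = fisher_enrich({"G0", "G1"}, {"G8", "G9"}, bg)
        assert ov == set()
        assert p == pytest.approx(1.0)

    def test_query_equals_background_is_certain(self):
        bg = {f"G{i}" for i in range(10)}
        pw = {f"G{i}" for i in range(5)}
        p, ov = fisher_enrich(bg, pw, bg)
        assert len(ov) == 5 and p == pytest.approx(1.0)

    def test_counting_worked_example(self):
        # background 10, pathway 5, query 4, overlap 4 -> 5/210
        bg = {f"G{i}" for i in range(10)}
        pw = {f"G{i}" for i in range(5)}
        q = {f"G{i}" for i in range(4)}
        p, _ = fisher_enrich(q, pw, bg)
        assert p == pytest.approx(5 / 210, rel=1e-10)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrich({"A"}, {"A"}, set())

    def test_matches_exhaustive_enumeration_small_backgrounds(self):
        # every configuration up to a 25-gene background
        for n_bg in (5, 12, 25):
            bg = {f"G{i}" for i in range(n_bg)}
            for k_pw, n_q in itertools.product((1, n_bg // 2, n_bg - 1), repeat=2):
                pw = {f"G{i}" for i in range(k_pw)}
                q = {f"G{i}" for i in range(n_bg - n_q, n_bg)}
                p, ov = fisher_enrich(q, pw, bg)
                expected = hypergeom_tail_by_enumeration(n_bg, k_pw, n_q, len(ov))
                assert p == pytest.approx(expected, rel=1e-9), (n_bg, k_pw, n_q)

    def test_matches_r_fisher_exact_oracle(self, tmp_path):
        """Cross-check the one-sided p against R's fisher.test on one table."""
        import subprocess

        bg = {f"G{i}" for i in range(40)}
        pw = {f"G{i}" for i in range(12)}
        q = {f"G{i}" for i in range(8, 22)}
        p, ov = fisher_enrich(q, pw, bg)
        a = len(ov)
        b = len(pw) - a
        c = len(q) - a
        d = len(bg) - a - b - c
        script = (f"cat(fisher.test(matrix(c({a},{b},{c},{d}),2,2),"
                  "alternative='greater')$p.value)")
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert p == pytest.approx(float(out.stdout.strip()), rel=1e-6)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.07])[0] == pytest.approx(0.07)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], rtol=1e-12)

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj <= 1.0)

    def test_tied_adjusted_block_signature(self):
        # a run of small raw p's sharing one adjusted value is the step-up
        # signature: p_adj[i] = min over j>=i of p_j * n/j
        raw = [7.19e-5, 1.94e-4, 2.20e-4, 2.22e-4, 2.42e-4, 9.23e-4, 2.02e-3]
        adj = bh_adjust(raw)
        assert len({round(v, 10) for v in adj[:5]}) == 1
        assert adj[5] > adj[4]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestRankZscore:
    def small_library(self):
        bg = {f"G{i}" for i in range(30)}
        lib = {
            "signal": {f"G{i}" for i in range(6)},
            "noiseA": {f"G{i}" for i in range(10, 16)},
            "noiseB": {f"G{i}" for i in range(16, 22)},
            "noiseC": {f"G{i}" for i in range(22, 28)},
        }
        return bg, lib

    def test_signal_pathway_better_than_expected_rank(self):
        bg, lib = self.small_library()
        query = {f"G{i}" for i in range(6)}  # exactly the signal pathway
        z = rank_zscore(query, lib, bg, n_null=300, rng=1)
        assert z["signal"] < 0

    def test_deterministic_given_seed(self):
        bg, lib = self.small_library()
        q = {"G0", "G1", "G10"}
        z1 = rank_zscore(q, lib, bg, n_null=100, rng=5)
        z2 = rank_zscore(q, lib, bg, n_null=100, rng=5)
        assert (z1 == z2).all()

    def test_needs_two_pathways(self):
        with pytest.raises(ValueError):
            rank_zscore({"A"}, {"only": {"A"}}, {"A", "B"}, n_null=10, rng=0)


class TestCombinedScore:
    @pytest.mark.parametrize("p_adj,z,expected", [
        (0.002277, -1.77, 10.77),
        (0.007232, -1.65, 8.13),
        (0.018769, -1.53, 6.08),
    ])
    def test_printed_worked_examples(self, p_adj, z, expected):
        assert combined_score(p_adj, z) == pytest.approx(expected, abs=0.005)

    def test_unit_case(self):
        assert combined_score(math.exp(-1), -1.0) == pytest.approx(1.0)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            combined_score(0.0, -1.0)


class TestEnrichQuery:
    def test_full_table_shape_and_ordering(self):
        bg = {f"G{i}" for i in range(40)}
        lib = {"A": {f"G{i}" for i in range(8)},
               "B": {f"G{i}" for i in range(20, 28)},
               "C": {f"G{i}" for i in range(30, 36)}}
        q = {f"G{i}" for i in range(6)}
        df = enrich_query(q, lib, bg, n_null=100, rng=3)
        assert list(df["pathway"])[0] == "A"
        assert (df["p"].diff().dropna() >= 0).all()
        assert df.loc[0, "overlap"] == "6/8"

    def test_null_queries_calibrated(self, rng):
        # fraction of pathway tests with p < 0.05 under random queries
        bg = sorted(f"G{i}" for i in range(60))
        lib = {f"P{j}": {f"G{i}" for i in rng.choice(60, 10, replace=False)}
               for j in range(10)}
        hits = total = 0
        for _ in range(500):
            q = {bg[i] for i in rng.choice(60, 8, replace=False)}
            for genes in lib.values():
                p, _ = fisher_enrich(q, genes, bg)
                hits += p < 0.05
                total += 1
        assert hits / total == pytest.approx(0.05, abs=0.03)
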