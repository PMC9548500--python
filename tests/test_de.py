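"""Wilcoxon rank-sum DE (exact and asymptotic), Bonferroni, GMT parsing and
hypergeometric over-representation."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sclonal as sc
from conftest import adata_from_dense


def brute_force_exact_p(x, y):
    """Literal enumeration of every group assignment of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n1)]
    total = comb(len(pooled), n1)
    n_le = sum(w <= w_obs + 1e-9 for w in sums)
    n_ge = sum(w >= w_obs - 1e-9 for w in sums)
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def norm_adata(values_a, values_b):
    """One-gene normalized AnnData with groups A and B (values already on log scale)."""
    col = np.concatenate([values_a, values_b]).reshape(-1, 1)
    adata = adata_from_dense(col, barcodes=[f"a{i}" for i in range(len(values_a))] + [f"b{i}" for i in range(len(values_b))])
    adata.uns["normalization"] = {"scale": 10_000.0, "log_base": "natural"}
    ga = [f"a{i}" for i in range(len(values_a))]
    gb = [f"b{i}" for i in range(len(values_b))]
    return adata, ga, gb


class TestWilcoxonExact:
    def test_canonical_example(self):
        assert sc.wilcoxon_exact_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(n1, 7)])
    def test_matches_brute_force_enumeration_tie_free(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(0.5, size=n2)
        assert sc.wilcoxon_exact_p(x, y) == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 3, size=rng.integers(2, 6)).astype(float)
            y = rng.integers(0, 3, size=rng.integers(2, 6)).astype(float)
            assert sc.wilcoxon_exact_p(x, y) == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        assert sc.wilcoxon_exact_p([1.0, 2.0, 3.0], [2.0, 1.0, 3.0]) == 1.0

    def test_approximation_close_to_exact_at_ten_per_group(self):
        """Tie-corrected normal approximation within 0.01 of exact at (10, 10)."""
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(100):
            x, y = rng.normal(size=10), rng.normal(0.8, size=10)
            exact = sc.wilcoxon_exact_p(x, y)
            approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            worst = max(worst, abs(exact - approx))
        assert worst < 0.01


class TestWilcoxonDE:
    def test_exact_branch_on_tiny_groups(self):
        adata, ga, gb = norm_adata([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        table = sc.wilcoxon_de(adata, ga, gb, min_pct=0.0, min_abs_log2fc_prefilter=0.0)
        assert table["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one_and_zero_log2fc(self):
        adata, ga, gb = norm_adata([1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0])
        table = sc.wilcoxon_de(adata, ga, gb, min_pct=0.0, min_abs_log2fc_prefilter=0.0)
        assert table["p_value"].iloc[0] == 1.0
        assert table["log2FC"].iloc[0] == 0.0

    def test_log2fc_formula(self):
        # linear means 3 and 1 with pseudocount 1 -> log2(4/2) = 1
        adata, ga, gb = norm_adata(np.log1p([3.0, 3.0]), np.log1p([1.0, 1.0]))
        table = sc.wilcoxon_de(adata, ga, gb, min_pct=0.0, min_abs_log2fc_prefilter=0.0)
        assert table["log2FC"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert table["mean_A"].iloc[0] == pytest.approx(3.0, abs=1e-12)

    def test_label_antisymmetry(self):
        rng = np.random.default_rng(8)
        X = np.log1p(rng.gamma(2.0, 2.0, size=(40, 15)))
        adata = adata_from_dense(X)
        adata.uns["normalization"] = {"scale": 10_000.0, "log_base": "natural"}
        cells = list(adata.obs_names)
        ab = sc.wilcoxon_de(adata, cells[:20], cells[20:], min_pct=0.0, min_abs_log2fc_prefilter=0.0)
        ba = sc.wilcoxon_de(adata, cells[20:], cells[:20], min_pct=0.0, min_abs_log2fc_prefilter=0.0)
        np.testing.assert_allclose(ab["log2FC"], -ba["log2FC"], atol=1e-12)
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-12)

    def test_prefilters_and_bonferroni_m(self):
        rng = np.random.default_rng(9)
        X = np.zeros((60, 3))
        X[:, 0] = np.log1p(rng.gamma(3.0, 2.0, size=60))          # expressed, similar
        X[:30, 1] = np.log1p(rng.gamma(6.0, 3.0, size=30))        # expressed, shifted
        X[30:, 1] = np.log1p(rng.gamma(1.0, 1.0, size=30))
        X[0, 2] = 0.01                                            # nearly never detected
        adata = adata_from_dense(X)
        adata.uns["normalization"] = {"scale": 10_000.0, "log_base": "natural"}
        cells = list(adata.obs_names)
        table = sc.wilcoxon_de(adata, cells[:30], cells[30:], min_pct=0.1, min_abs_log2fc_prefilter=0.25)
        assert not table["tested"].loc["gene3"]           # fails min_pct
        assert np.isnan(table.loc["gene3", "p_value"])
        m = int(table["tested"].sum())
        tested = table[table["tested"]]
        np.testing.assert_allclose(tested["p_adj"], np.minimum(1.0, tested["p_value"] * m))

    def test_group_overlap_rejected(self):
        adata, ga, gb = norm_adata([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="overlap"):
            sc.wilcoxon_de(adata, ga, ga)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 100, 1.0), (1e-5, 2000, 0.02), (0.0, 50, 0.0)]
    )
    def test_examples(self, p, m, expected):
        assert sc.bonferroni_adjust([p], m)[0] == pytest.approx(expected, abs=1e-15)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.integers(30, 5000))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_capped_and_monotone(self, ps, m):
        adj = sc.bonferroni_adjust(ps, m)
        assert ((adj >= np.asarray(ps) - 1e-15) & (adj <= 1.0)).all()


class TestReadGmt:
    def test_parse_and_dedup(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tA\tB\tC\nS2\td\tA\tA\tB\n")
        sets = sc.read_gmt(path)
        assert sets["S1"] == {"A", "B", "C"}
        assert sets["S2"] == {"A", "B"}

    def test_duplicate_name_error(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\td\tA\tB\nS1\td\tC\tD\n")
        with pytest.raises(ValueError, match="line 2"):
            sc.read_gmt(path)

    def test_short_line_error_names_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\td\tA\nS2\tonly-two-fields\n")
        with pytest.raises(ValueError, match="line 2"):
            sc.read_gmt(path)


def hypergeom_upper_tail_brute(M, K, n, k):
    """Sum of the hypergeometric mass for x = k .. min(K, n)."""
    return sum(comb(K, x) * comb(M - K, n - x) / comb(M, n) for x in range(k, min(K, n) + 1))


class TestOraEnrichment:
    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        table = sc.ora_enrichment(["g0"], universe, {"S": {"g10", "g11"}})
        assert table.loc["S", "p"] == pytest.approx(1.0)

    def test_de_equals_universe_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"S": {"g1", "g2", "g3"}}
        table = sc.ora_enrichment(universe, universe, sets)
        assert table.loc["S", "k"] == table.loc["S", "K"]
        assert table.loc["S", "p"] == pytest.approx(1.0)

    def test_matches_brute_force_mass_summation(self):
        """M=100, K=10, n=10, k=5 plus randomized configurations, to 1e-12."""
        universe = [f"g{i}" for i in range(100)]
        sets = {"S": set(universe[:10])}
        de = universe[:5] + universe[50:55]  # k=5 of the set, n=10
        table = sc.ora_enrichment(de, universe, sets)
        assert table.loc["S", "p"] == pytest.approx(hypergeom_upper_tail_brute(100, 10, 10, 5), abs=1e-12)

        rng = np.random.default_rng(17)
        for _ in range(20):
            M = int(rng.integers(20, 200))
            K = int(rng.integers(1, M // 2))
            n = int(rng.integers(1, M // 2))
            uni = [f"g{i}" for i in range(M)]
            gene_set = set(rng.choice(uni, size=K, replace=False))
            de_genes = list(rng.choice(uni, size=n, replace=False))
            k = len(gene_set & set(de_genes))
            table = sc.ora_enrichment(de_genes, uni, {"S": gene_set})
            assert table.loc["S", "p"] == pytest.approx(hypergeom_upper_tail_brute(M, K, n, k), abs=1e-12)

    def test_bh_qvalues_match_step_up_reference(self):
        """q-values equal an independent implementation of the BH step-up rule."""
        rng = np.random.default_rng(23)
        universe = [f"g{i}" for i in range(200)]
        sets = {f"S{j}": set(rng.choice(universe, size=rng.integers(5, 40), replace=False)) for j in range(12)}
        de = list(rng.choice(universe, size=30, replace=False))
        table = sc.ora_enrichment(de, universe, sets)

        p = table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(table["q"].to_numpy(), expected, atol=1e-12)

    def test_de_outside_universe_warned_and_dropped(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="outside"):
            table = sc.ora_enrichment(["g1", "zz"], universe, {"S": {"g1"}})
        assert table.loc["S", "n"] == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            sc.ora_enrichment([], [], {"S": {"a"}})


class TestDEPower:
    def test_shifted_genes_recovered_with_bonferroni_control(self):
        """50 genes at a true 2x shift vs 1000 null genes, 200 cells/group:
        >= 80% of shifted genes recovered, <= 1 null gene called."""
        ann = sc.make_genome(7, 150, 0, 0, seed=21)
        # 2x shift on the first 50 genes of chromosome 1 for group A
        clone = sc.CloneSpec("up", (("1", 1, 5_000_000, 2.0),))
        plans = [sc.CellPlan("S", {"A": 200, "B": 200}, {"A": "up"},
                             library_size_log_mean=np.log(5000.0))]
        ds = sc.simulate_tumor_counts(ann, [clone], plans, baseline_mean_shape=2.0, seed=21)
        norm = sc.lognormalize(ds.counts)
        obs = ds.counts.obs
        ga = list(obs.index[obs.cell_class == "A"])
        gb = list(obs.index[obs.cell_class == "B"])
        table = sc.wilcoxon_de(norm, ga, gb)

        shifted = (ds.annotation["chromosome"] == "1") & (ds.annotation["start"] <= 5_000_000)
        shifted = shifted.reindex(table.index).fillna(False)
        hit = (table["p_adj"] < 0.05) & (table["log2FC"].abs() > np.log2(1.5))
        hit = hit.fillna(False)
        assert hit[shifted].mean() >= 0.80
        assert hit[~shifted].sum() <= 1
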