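import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from coexnet.network import COLOR_PALETTE

from conftest import make_expr


def tom_triple_loop(a: np.ndarray) -> np.ndarray:
    """O(n^3) reference implementation of topological overlap."""
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return out


class TestAdjacency:
    def test_identical_genes_have_unit_adjacency(self):
        expr = make_expr([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        for power in (1, 6):
            adj = cx.build_adjacency(expr, power)
            assert adj.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_unsigned_vs_signed(self):
        expr = make_expr([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        assert cx.build_adjacency(expr, 6, mode="unsigned").values[0, 1] == pytest.approx(1.0)
        assert cx.build_adjacency(expr, 6, mode="signed").values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(size=(10, 25)))
        for mode in ("unsigned", "signed"):
            adj = cx.build_adjacency(expr, 3, mode=mode)
            cor = np.corrcoef(expr.values)
            expected = (
                np.abs(cor) ** 3 if mode == "unsigned" else ((1 + cor) / 2) ** 3
            )
            np.fill_diagonal(expected, 1.0)
            assert np.max(np.abs(adj.values - expected)) <= 1e-12

    def test_zero_variance_gene_named(self):
        expr = make_expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], genes=["FLAT", "OK"])
        with pytest.raises(ValueError, match="FLAT"):
            cx.build_adjacency(expr, 2)


class TestTopologicalOverlap:
    def test_three_node_path_by_hand(self):
        # a12 = a23 = 1, a13 = 0: TOM_12 = 1, TOM_13 = 0.5
        a = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]],
            index=list("xyz"), columns=list("xyz"),
        )
        tom = cx.topological_overlap(a)
        assert tom.loc["x", "y"] == pytest.approx(1.0)
        assert tom.loc["x", "z"] == pytest.approx(0.5)

    def test_disconnected_graph_has_zero_overlap(self):
        a = pd.DataFrame(np.eye(4))
        tom = cx.topological_overlap(a)
        off = tom.values[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0)

    @pytest.mark.parametrize("n", [5, 15, 20])
    def test_matches_triple_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        raw = rng.uniform(0, 1, size=(n, n))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.topological_overlap(pd.DataFrame(a))
        assert np.max(np.abs(tom.values - tom_triple_loop(a))) <= 1e-12

    def test_asymmetric_input_rejected(self):
        a = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cx.topological_overlap(a)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 1, size=(12, 12))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.topological_overlap(pd.DataFrame(a)).values
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestDetectModules:
    def test_two_identical_blocks_split_perfectly(self):
        rng = np.random.default_rng(3)
        base1, base2 = rng.normal(size=20), rng.normal(size=20)
        rows = [base1] * 5 + [base2] * 5
        noise = rng.normal(scale=1e-6, size=(10, 20))
        expr = make_expr(np.array(rows) + noise)
        tom = cx.topological_overlap(cx.build_adjacency(expr, 6))
        # near-zero within-block heights: cut above them but below the
        # block-joining merge
        modules = cx.detect_modules(tom, min_module_size=3, cut_quantile=0.9)
        assert modules.nunique() == 2
        assert len(set(modules.iloc[:5])) == 1
        assert len(set(modules.iloc[5:])) == 1

    def test_pure_noise_is_all_grey(self):
        n_ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            expr = make_expr(rng.normal(size=(100, 80)))
            tom = cx.topological_overlap(cx.build_adjacency(expr, 6))
            modules = cx.detect_modules(tom, min_module_size=30)
            n_ok += int((modules == cx.GREY).all())
        assert n_ok >= 9

    def test_min_size_validated(self):
        tom = pd.DataFrame(np.eye(5))
        with pytest.raises(ValueError, match="min_module_size"):
            cx.detect_modules(tom, min_module_size=2)

    def test_labels_come_from_palette(self, detected):
        modules, _, _ = detected
        assert set(modules.unique()) <= set(COLOR_PALETTE) | {cx.GREY}

    def test_gene_permutation_equivariance(self):
        expr, truth = cx.simulate_cohort(n_genes=120, n_samples=100, n_modules=2,
                                         module_size=40, seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.index)
        tom = cx.topological_overlap(cx.build_adjacency(expr, 6))
        tom_p = cx.topological_overlap(cx.build_adjacency(expr.loc[perm], 6))
        m = cx.detect_modules(tom, min_module_size=20)
        m_p = cx.detect_modules(tom_p, min_module_size=20)
        pd.testing.assert_series_equal(m.sort_index(), m_p.sort_index())


class TestEigengenes:
    def test_module_of_identical_genes(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=30)
        expr = make_expr(np.vstack([base, base, base]))
        modules = pd.Series(["turquoise"] * 3, index=expr.index)
        eig = cx.compute_eigengenes(expr, modules)
        assert eig.variance_explained["turquoise"] == pytest.approx(1.0)
        cor = np.corrcoef(eig.values.loc["turquoise"], expr.iloc[0])[0, 1]
        assert cor == pytest.approx(1.0)

    def test_anticorrelated_pair_orientation(self):
        """2x2 case solvable by hand: eigengene = (z1 - z2)/sqrt(2) up to sign;
        it correlates +1 with one gene, -1 with the other, oriented to mean >= 0."""
        rng = np.random.default_rng(8)
        base = rng.normal(size=40)
        expr = make_expr(np.vstack([base, -base + 1e-9 * rng.normal(size=40)]))
        modules = pd.Series(["blue", "blue"], index=expr.index)
        eig = cx.compute_eigengenes(expr, modules)
        e = eig.values.loc["blue"].values
        c1 = np.corrcoef(e, expr.iloc[0])[0, 1]
        c2 = np.corrcoef(e, expr.iloc[1])[0, 1]
        assert sorted([round(c1, 6), round(c2, 6)]) == [-1.0, 1.0]
        assert (c1 + c2) / 2 >= -1e-9
        assert eig.variance_explained["blue"] == pytest.approx(1.0, abs=1e-6)

    def test_variance_explained_in_unit_interval(self, detected):
        _, eig, _ = detected
        ve = eig.variance_explained
        assert ((ve >= 0) & (ve <= 1)).all()

    def test_eigengene_unit_variance(self, detected):
        _, eig, _ = detected
        assert np.allclose(eig.values.var(axis=1, ddof=1), 1.0)

    def test_singleton_module_rejected(self):
        expr = make_expr([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]])
        modules = pd.Series(["red", cx.GREY], index=expr.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            cx.compute_eigengenes(expr, modules)


class TestModuleMembership:
    def test_gene_equal_to_eigengene_has_unit_kme(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=50)
        expr = make_expr(np.vstack([base, base * 2 + 1]))
        modules = pd.Series(["turquoise"] * 2, index=expr.index)
        eig = cx.compute_eigengenes(expr, modules)
        kme = cx.module_membership(expr, eig)
        assert np.allclose(np.abs(kme.values), 1.0)

    def test_matches_direct_correlation_oracle(self, detected, default_cohort):
        expr, _ = default_cohort
        _, eig, kme = detected
        sub = expr.iloc[:40]
        for m in eig.values.index[:2]:
            direct = [
                np.corrcoef(sub.loc[g], eig.values.loc[m])[0, 1] for g in sub.index
            ]
            assert np.max(np.abs(kme.loc[sub.index, m].values - direct)) <= 1e-12

    def test_independent_noise_gene_has_small_kme(self):
        highs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=500)
            mat = np.vstack([base + rng.normal(scale=0.1, size=500),
                             base + rng.normal(scale=0.1, size=500),
                             rng.normal(size=500)])
            expr = make_expr(mat)
            modules = pd.Series(["blue", "blue", cx.GREY], index=expr.index)
            eig = cx.compute_eigengenes(expr, modules)
            kme = cx.module_membership(expr, eig)
            highs.append(abs(kme.iloc[2, 0]))
        assert max(highs) < 0.15


class TestHubGenes:
    def test_planted_hubs_recovered(self, detected, default_cohort):
        from conftest import match_modules

        _, truth = default_cohort
        modules, _, kme = detected
        mapping = match_modules(modules, truth.module_labels)
        hubs = cx.hub_genes(kme, modules, top_n=5)
        n_hit = 0
        for det, planted in mapping.items():
            top3_planted = truth.module_genes(planted)[:3]  # loadings decrease
            n_hit += int(set(top3_planted) <= set(hubs[det]))
        assert n_hit >= 0.8 * len(mapping)

    def test_top_n_larger_than_module_returns_whole_module(self):
        kme = pd.DataFrame({"red": [0.9, 0.8]}, index=["G1", "G2"])
        modules = pd.Series(["red", "red"], index=["G1", "G2"])
        assert cx.hub_genes(kme, modules, top_n=10)["red"] == ["G1", "G2"]

    def test_kme_ties_broken_lexicographically(self):
        kme = pd.DataFrame({"red": [0.5, 0.5]}, index=["B", "A"])
        modules = pd.Series(["red", "red"], index=["B", "A"])
        assert cx.hub_genes(kme, modules, top_n=1)["red"] == ["A"]

    def test_exactly_one_rule_required(self):
        kme = pd.DataFrame({"red": [0.5]}, index=["A"])
        modules = pd.Series(["red"], index=["A"])
        with pytest.raises(ValueError, match="exactly one"):
            cx.hub_genes(kme, modules)


class TestMergeCloseModules:
    def _split_module_expr(self):
        rng = np.random.default_rng(4)
        factor = rng.normal(size=150)
        mat = factor[None, :] * np.linspace(1, 0.7, 40)[:, None]
        mat = mat + rng.normal(scale=0.3, size=(40, 150))
        return make_expr(mat)

    def test_duplicate_module_merged(self):
        expr = self._split_module_expr()
        # same latent factor artificially split into two labels
        modules = pd.Series(["turquoise"] * 20 + ["blue"] * 20, index=expr.index)
        merged = cx.merge_close_modules(expr, modules, merge_corr=0.75)
        assert merged.nunique() == 1

    def test_orthogonal_factors_not_merged(self):
        expr, truth = cx.simulate_cohort(n_genes=120, n_samples=150, n_modules=2,
                                         module_size=40, seed=9)
        modules = truth.module_labels.map(lambda m: {0: cx.GREY, 1: "turquoise", 2: "blue"}[m])
        merged = cx.merge_close_modules(expr, modules, merge_corr=0.75)
        assert set(merged.unique()) == {"turquoise", "blue", cx.GREY}

    def test_idempotent(self):
        expr = self._split_module_expr()
        modules = pd.Series(["turquoise"] * 20 + ["blue"] * 20, index=expr.index)
        once = cx.merge_close_modules(expr, modules, merge_corr=0.75)
        twice = cx.merge_close_modules(expr, once, merge_corr=0.75)
        pd.testing.assert_series_equal(once, twice)


class TestSoftThreshold:
    def test_report_covers_requested_powers(self, default_cohort):
        expr, _ = default_cohort
        rep = cx.pick_soft_threshold(expr.iloc[:300], powers=[2, 4, 6])
        assert list(rep.table["power"]) == [2, 4, 6]

    def test_requires_minimum_size(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="genes"):
            cx.pick_soft_threshold(make_expr(rng.normal(size=(10, 30))))

    def test_chosen_power_stable_across_seeds(self):
        powers = []
        for seed in range(10):
            expr, _ = cx.simulate_cohort(n_genes=400, n_samples=150, n_modules=3,
                                         module_size=50, seed=seed)
            rep = cx.pick_soft_threshold(expr, powers=range(1, 13))
            powers.append(rep.chosen_power)
        mode = max(set(powers), key=powers.count)
        assert powers.count(mode) >= 8
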