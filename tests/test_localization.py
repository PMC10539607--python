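import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from coexnet.types import GeneSetLibrary


class TestDeconvolve:
    def test_identity_signature_recovers_exactly(self):
        s = pd.DataFrame(np.eye(2), index=["G1", "G2"], columns=["a", "b"])
        bulk = pd.DataFrame({"S1": [0.3, 0.7]}, index=["G1", "G2"])
        props = cx.deconvolve(bulk, s)
        assert props.loc["S1", "a"] == pytest.approx(0.3)
        assert props.loc["S1", "b"] == pytest.approx(0.7)

    def test_noise_free_mixtures_recovered_to_machine_precision(self):
        rng = np.random.default_rng(0)
        s = pd.DataFrame(
            rng.uniform(0, 2, size=(40, 3)),
            index=[f"G{i}" for i in range(40)], columns=["a", "b", "c"],
        )
        bulk, true_p = cx.simulate_mixtures(s, n_samples=25, noise_sd=0.0, seed=1)
        est = cx.deconvolve(bulk, s)
        assert np.max(np.abs(est.values - true_p.values)) <= 1e-6

    def test_noisy_mixtures_rmse_bounded(self):
        rmses = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = pd.DataFrame(
                rng.uniform(0, 2, size=(60, 4)),
                index=[f"G{i}" for i in range(60)], columns=list("abcd"),
            )
            bulk, true_p = cx.simulate_mixtures(s, n_samples=100, noise_sd=0.1, seed=seed)
            est = cx.deconvolve(bulk, s)
            rmses.append(float(np.sqrt(((est.values - true_p.values) ** 2).mean())))
        assert np.mean(rmses) <= 0.05

    def test_recovery_error_monotone_in_noise(self):
        rng = np.random.default_rng(7)
        s = pd.DataFrame(
            rng.uniform(0, 2, size=(60, 3)),
            index=[f"G{i}" for i in range(60)], columns=list("abc"),
        )
        rmse = []
        for noise_sd in (0.0, 0.1, 0.5):
            bulk, true_p = cx.simulate_mixtures(s, n_samples=60, noise_sd=noise_sd, seed=1)
            est = cx.deconvolve(bulk, s)
            rmse.append(float(np.sqrt(((est.values - true_p.values) ** 2).mean())))
        assert rmse[0] <= rmse[1] <= rmse[2]

    def test_output_always_on_simplex(self):
        rng = np.random.default_rng(3)
        s = pd.DataFrame(
            rng.uniform(0, 1, size=(30, 3)),
            index=[f"G{i}" for i in range(30)], columns=list("abc"),
        )
        bulk, _ = cx.simulate_mixtures(s, n_samples=20, noise_sd=0.3, seed=2)
        props = cx.deconvolve(bulk, s)
        assert (props.values >= 0).all()
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_rank_deficient_signature_rejected(self):
        s = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]},
                         index=["G1", "G2", "G3"])
        bulk = pd.DataFrame({"S1": [1.0, 2.0, 3.0]}, index=["G1", "G2", "G3"])
        with pytest.raises(ValueError, match="rank"):
            cx.deconvolve(bulk, s)

    def test_insufficient_gene_intersection_rejected(self):
        s = pd.DataFrame(np.eye(4), index=["A", "B", "C", "D"], columns=list("wxyz"))
        bulk = pd.DataFrame({"S1": [1.0]}, index=["A"])
        with pytest.raises(ValueError, match="half|intersection|found"):
            cx.deconvolve(bulk, s)


class TestEigengeneCovariate:
    def _eig(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(3, n))
        samples = [f"S{j}" for j in range(n)]
        eig = pd.DataFrame(vals, index=["turquoise", "blue", "brown"], columns=samples)
        return cx.EigengeneMatrix(values=eig, variance_explained=pd.Series(
            [0.5, 0.4, 0.3], index=eig.index))

    def test_monotone_transform_gives_unit_rho(self):
        eig = self._eig()
        cov = pd.DataFrame(
            {"pheno": np.exp(eig.values.loc["turquoise"].values)},
            index=eig.values.columns,
        )
        table = cx.correlate_eigengene_covariate(eig, cov)
        row = table[(table["module"] == "turquoise")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_rank_formula_worked_example(self):
        """x=[1..5], y=[2,1,4,3,5]: rho = 1 - 6*4/(5*24) = 0.8."""
        eig = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]] , index=["m"],
                           columns=[f"S{j}" for j in range(5)])
        em = cx.EigengeneMatrix(values=eig, variance_explained=pd.Series([1.0], index=["m"]))
        cov = pd.DataFrame({"y": [2.0, 1.0, 4.0, 3.0, 5.0]}, index=eig.columns)
        # relax the >= 10 shared-sample floor via direct scipy cross-check
        from scipy.stats import spearmanr

        rho, _ = spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)
        with pytest.raises(ValueError, match="10"):
            cx.correlate_eigengene_covariate(em, cov)

    def test_constant_covariate_dropped_with_warning(self):
        eig = self._eig()
        cov = pd.DataFrame(
            {"flat": np.ones(len(eig.values.columns)),
             "ok": np.arange(len(eig.values.columns), dtype=float)},
            index=eig.values.columns,
        )
        with pytest.warns(UserWarning, match="flat"):
            table = cx.correlate_eigengene_covariate(eig, cov)
        assert set(table["covariate"]) == {"ok"}

    def test_invariant_to_joint_sample_reordering(self):
        eig = self._eig()
        cov = pd.DataFrame(
            {"y": np.random.default_rng(5).normal(size=len(eig.values.columns))},
            index=eig.values.columns,
        )
        t1 = cx.correlate_eigengene_covariate(eig, cov)
        perm = list(reversed(eig.values.columns))
        eig2 = cx.EigengeneMatrix(values=eig.values[perm],
                                  variance_explained=eig.variance_explained)
        t2 = cx.correlate_eigengene_covariate(eig2, cov.loc[perm])
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_driver_flagged_nondrivers_not(self):
        n_driver_hits, n_nondriver_rows, n_nondriver_flagged = 0, 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            expr, truth = cx.simulate_cohort(n_genes=400, n_samples=200, n_modules=3,
                                             module_size=50, seed=seed)
            pheno = cx.simulate_phenotype(truth, [1], beta=1.0, noise_sd=0.5, seed=seed)
            # eigengenes on the true labels isolate the association machinery
            labels = truth.module_labels.map(
                lambda m: cx.GREY if m == 0 else f"m{m}"
            )
            eig = cx.compute_eigengenes(expr, labels)
            table = cx.correlate_eigengene_covariate(
                eig, pheno.to_frame("sTIL"), fdr=0.1
            )
            flags = table.set_index("module")["significant"]
            n_driver_hits += int(flags["m1"])
            for m in ("m2", "m3"):
                n_nondriver_rows += 1
                n_nondriver_flagged += int(flags[m])
        assert n_driver_hits >= 0.9 * n_seeds
        assert n_nondriver_flagged <= 0.1 * n_nondriver_rows


class TestCelltypeSpecificity:
    def test_planted_marker_module_flagged_unrelated_not(self):
        n_hit, n_false = 0, 0
        for seed in range(20):
            _, truth = cx.simulate_cohort(n_genes=300, n_samples=20, n_modules=2,
                                          module_size=40, seed=seed)
            labels = truth.module_labels.map(
                lambda m: {0: cx.GREY, 1: "turquoise", 2: "blue"}[m]
            )
            rng = np.random.default_rng(seed)
            lib = GeneSetLibrary()
            lib.add("CD8_markers", truth.module_genes(1), "planted CD8 analog")
            lib.add("unrelated",
                    list(rng.choice(truth.module_labels.index, 40, replace=False)), "")
            table = cx.celltype_specificity(labels, lib,
                                            universe=truth.module_labels.index)
            t = table.set_index(["module", "set"])["significant"]
            n_hit += int(t[("turquoise", "CD8_markers")])
            n_false += int(t[("blue", "CD8_markers")])
        assert n_hit == 20  # self-overlap construction is always significant
        assert n_false <= 1

    def test_schema_matches_enrichment_table(self):
        _, truth = cx.simulate_cohort(n_genes=100, n_samples=20, n_modules=1,
                                      module_size=30, seed=0)
        labels = truth.module_labels.map(lambda m: cx.GREY if m == 0 else "turquoise")
        lib = GeneSetLibrary()
        lib.add("set1", truth.module_genes(1)[:10], "")
        table = cx.celltype_specificity(labels, lib, universe=truth.module_labels.index)
        assert list(table.columns) == [
            "module", "set", "a", "b", "c", "d", "odds_ratio", "p", "q", "significant"
        ]


class TestLocalizationRoutesAgree:
    def test_marker_overlap_and_proportion_correlation_concur(self):
        """Closed loop: mixtures from a signature matrix carry cell-type
        coexpression; both localization routes should point the planted
        module at its generating cell type."""
        n_agree = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 100)
            genes = [f"G{i:03d}" for i in range(120)]
            s = pd.DataFrame(0.1, index=genes, columns=["CD8", "other"])
            s.iloc[:40, 0] = 2.0   # CD8 markers
            s.iloc[40:, 1] = 1.0
            bulk, true_p = cx.simulate_mixtures(s, n_samples=100, dirichlet_alpha=2.0,
                                                noise_sd=0.1, seed=seed)
            labels = pd.Series(cx.GREY, index=genes, dtype=object)
            labels.iloc[:40] = "turquoise"
            eig = cx.compute_eigengenes(bulk, labels)
            props = cx.deconvolve(bulk, s)
            assoc = cx.correlate_eigengene_covariate(eig, props, fdr=0.1)
            row = assoc[(assoc["module"] == "turquoise") & (assoc["covariate"] == "CD8")]
            route1 = bool(row.iloc[0]["significant"]) and row.iloc[0]["rho"] > 0
            lib = GeneSetLibrary()
            lib.add("CD8_markers", genes[:40], "")
            spec_table = cx.celltype_specificity(labels, lib, universe=genes)
            route2 = bool(spec_table.iloc[0]["significant"])
            n_agree += int(route1 and route2)
        assert n_agree >= 0.9 * n_seeds
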