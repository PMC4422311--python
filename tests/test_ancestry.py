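"""Admixture likelihood fitting, K selection and PCA."""

import io

import numpy as np
import pytest

from lineagekit import ancestry, synthgen
from lineagekit.ancestry import (GenotypeMatrix, ReferencePanel,
                                 admixture_fit, choose_k, pca_project,
                                 read_genotype_table, summarize_ancestry,
                                 write_genotype_table)


def small_panel(fst=0.3, n_study=30, seed=7, ref=(30, 30, 30)):
    spec = synthgen.AdmixSimSpec(fst=fst, n_study=n_study, seed=seed,
                                 ref_sizes=ref)
    P = synthgen.sim_reference_freqs(spec)
    return spec, synthgen.sim_admixed_genotypes(P, spec)


def aligned_q(fit, spec):
    lab2k = {lab: k for k, lab in enumerate(fit.component_labels)}
    return fit.Q[:, [lab2k[lab] for lab in spec.ref_labels]]


class TestAdmixtureFit:
    def test_fixed_difference_marker_forces_one_hot(self):
        # one marker fixed 1/0/0 across three reference pops; a study
        # individual with dosage 2 must be assigned entirely to pop 1
        inds = ["r1", "r2", "r3", "s"]
        labels = ["AFR", "EUR", "AME", "study"]
        dosage = np.array([[2.0], [0.0], [0.0], [2.0]])
        G = GenotypeMatrix(inds, labels, ["m1"], dosage)
        refs = ReferencePanel(G.subset([0, 1, 2]))
        fit = admixture_fit(G, K=3, refs=refs, supervised=True,
                            max_iter=5000, tol=1e-12)
        k_afr = fit.component_labels.index("AFR")
        assert fit.Q[3, k_afr] > 0.99

    def test_loglik_trace_non_decreasing(self):
        spec, (G, Qtrue, panel) = small_panel()
        for sup in (False, True):
            fit = admixture_fit(G, 3, refs=panel, supervised=sup,
                                seed=3, max_iter=300)
            diffs = np.diff(fit.log_likelihood_trace)
            assert np.all(diffs >= -1e-6)

    def test_q_rows_sum_to_one_p_in_bounds(self):
        spec, (G, Qtrue, panel) = small_panel()
        fit = admixture_fit(G, 3, refs=panel, seed=0, max_iter=200)
        assert np.allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
        assert fit.P.min() >= 0 and fit.P.max() <= 1

    def test_recovery_close_to_known_p_oracle(self):
        spec, (G, Qtrue, panel) = small_panel(fst=0.3, n_study=40)
        fit = admixture_fit(G, 3, refs=panel, seed=1)
        Qhat = aligned_q(fit, spec)
        study = np.array(G.labels) == "study"
        mae = np.abs(Qhat[study] - Qtrue[study]).mean()
        # well under the statistical noise floor of a 46-marker panel
        assert mae < 0.15

    def test_supervised_and_unsupervised_agree(self):
        spec, (G, Qtrue, panel) = small_panel(fst=0.5, n_study=40,
                                              ref=(60, 60, 60))
        fu = admixture_fit(G, 3, refs=panel, supervised=False, seed=2)
        fs = admixture_fit(G, 3, refs=panel, supervised=True, seed=2)
        qu, qs = aligned_q(fu, spec), aligned_q(fs, spec)
        study = np.array(G.labels) == "study"
        assert np.abs(qu[study] - qs[study]).mean() < 0.02

    def test_missing_entries_ignored(self):
        spec, (G, Qtrue, panel) = small_panel()
        X = G.dosages.copy()
        rng = np.random.default_rng(0)
        mask = rng.random(X.shape) < 0.1
        X[mask] = np.nan
        Gm = GenotypeMatrix(G.individuals, G.labels, G.markers, X)
        fit = admixture_fit(Gm, 3, refs=panel, seed=0, max_iter=200)
        assert np.isfinite(fit.log_likelihood_trace[-1])
        assert np.allclose(fit.Q.sum(axis=1), 1.0)

    def test_monomorphic_markers_excluded_with_warning(self):
        spec, (G, Qtrue, panel) = small_panel()
        X = np.column_stack([G.dosages, np.ones(G.n)])
        Gm = GenotypeMatrix(G.individuals, G.labels,
                            G.markers + ["mono"], X)
        with pytest.warns(UserWarning, match="monomorphic"):
            fit = admixture_fit(Gm, 3, refs=panel, seed=0, max_iter=50)
        assert len(fit.kept_markers) == G.m

    def test_supervised_k_exceeding_labels_errors(self):
        spec, (G, Qtrue, panel) = small_panel()
        with pytest.raises(ValueError, match="supervised"):
            admixture_fit(G, 4, refs=panel, supervised=True)

    def test_k_below_two_rejected(self):
        spec, (G, Qtrue, panel) = small_panel()
        with pytest.raises(ValueError):
            admixture_fit(G, 1)

    def test_deterministic_given_seed(self):
        spec, (G, Qtrue, panel) = small_panel()
        a = admixture_fit(G, 3, refs=panel, seed=5, max_iter=100)
        b = admixture_fit(G, 3, refs=panel, seed=5, max_iter=100)
        assert np.array_equal(a.Q, b.Q) and np.array_equal(a.P, b.P)


class TestSummarize:
    def test_single_individual_passthrough(self):
        out = summarize_ancestry(np.array([[0.5, 0.3, 0.2]]), ["g"])
        assert np.allclose(out["g"], [0.5, 0.3, 0.2])

    def test_one_hot_groups(self):
        Q = np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0]], float)
        out = summarize_ancestry(Q, ["a", "a", "b", "b"])
        assert np.allclose(out["a"], [1, 0, 0])
        assert np.allclose(out["b"], [0, 1, 0])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            summarize_ancestry(np.eye(2), ["a", "b"], groups=["a"])

    def test_group_means_recovered_for_fixed_truth(self):
        # Native-American-dominant group simulated at (0.92, 0.08, 0.00)
        spec = synthgen.AdmixSimSpec(
            fst=0.5, n_study=60, seed=11, q_mode="fixed",
            q_fixed=(0.0, 0.08, 0.92), ref_sizes=(60, 60, 60))
        P = synthgen.sim_reference_freqs(spec)
        G, Qtrue, panel = synthgen.sim_admixed_genotypes(P, spec)
        fit = admixture_fit(G, 3, refs=panel, supervised=True, seed=4)
        Qhat = aligned_q(fit, spec)
        means = summarize_ancestry(Qhat, G.labels)
        assert np.abs(means["study"] - np.array([0.0, 0.08, 0.92])
                      ).max() < 0.03


class TestChooseK:
    def test_argmin_at_three_for_three_pops(self):
        spec = synthgen.AdmixSimSpec(fst=0.4, n_study=30, seed=2,
                                     ref_sizes=(40, 40, 40))
        P = synthgen.sim_reference_freqs(spec)
        G, _, panel = synthgen.sim_admixed_genotypes(P, spec)
        errors, best = choose_k(G, panel, k_range=(2, 3, 4), folds=3,
                                seed=0, max_iter=150)
        assert best == 3

    def test_homogeneous_data_prefers_k1(self):
        rng = np.random.default_rng(8)
        freqs = rng.uniform(0.2, 0.8, size=40)
        X = rng.binomial(2, freqs, size=(60, 40)).astype(float)
        G = GenotypeMatrix([f"i{j}" for j in range(60)], ["g"] * 60,
                           [f"m{j}" for j in range(40)], X)
        errors, best = choose_k(G, None, k_range=(1, 2), folds=3,
                                seed=0, max_iter=100)
        assert errors[1] <= errors[2] * 1.05

    def test_deterministic_given_seed(self):
        spec, (G, _, panel) = small_panel(n_study=15)
        a = choose_k(G, panel, k_range=(2, 3), folds=2, seed=9,
                     max_iter=50)
        b = choose_k(G, panel, k_range=(2, 3), folds=2, seed=9,
                     max_iter=50)
        assert a == b

    def test_too_few_folds_rejected(self):
        spec, (G, _, panel) = small_panel(n_study=5)
        with pytest.raises(ValueError):
            choose_k(G, panel, k_range=(2,), folds=1)


class TestPca:
    def test_fixed_difference_clusters_separate_on_pc1(self):
        n = 20
        X = np.zeros((2 * n, 10))
        X[n:, :] = 2.0
        rng = np.random.default_rng(0)
        X += rng.binomial(1, 0.05, size=X.shape)  # slight noise
        X = np.clip(X, 0, 2)
        G = GenotypeMatrix([f"i{j}" for j in range(2 * n)],
                           ["a"] * n + ["b"] * n,
                           [f"m{j}" for j in range(10)], X)
        res = pca_project(G, 2)
        pc1 = res.scores[:, 0]
        assert max(pc1[:n]) < min(pc1[n:]) or max(pc1[n:]) < min(pc1[:n])

    def test_reference_clusters_form_disjoint_hulls(self):
        spec, (G, _, panel) = small_panel(fst=0.2, n_study=0)
        res = pca_project(panel.genotypes, 2)
        labs = np.array(panel.genotypes.labels)
        # convex-hull disjointness proxy: nearest centroid classifies all
        cents = {g: res.scores[labs == g].mean(axis=0)
                 for g in ("AFR", "EUR", "AME")}
        for i, lab in enumerate(labs):
            d = {g: np.linalg.norm(res.scores[i] - c)
                 for g, c in cents.items()}
            assert min(d, key=d.get) == lab

    def test_constant_shift_of_a_marker_leaves_scores_unchanged(self):
        spec, (G, _, panel) = small_panel(n_study=10)
        res1 = pca_project(G, 2)
        X = G.dosages.copy()
        # recode marker 0 to the other allele (2 - dosage)
        X[:, 0] = 2.0 - X[:, 0]
        res2 = pca_project(GenotypeMatrix(G.individuals, G.labels,
                                          G.markers, X), 2)
        # centering removes the shift; the flip only reflects the loading
        assert np.allclose(np.abs(res1.scores), np.abs(res2.scores),
                           atol=1e-8)

    def test_explained_variance_non_increasing(self):
        spec, (G, _, panel) = small_panel()
        res = pca_project(G, 5)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_all_missing_marker_dropped(self):
        X = np.array([[0.0, np.nan], [2.0, np.nan], [1.0, np.nan]])
        G = GenotypeMatrix(["a", "b", "c"], ["g"] * 3, ["m1", "m2"], X)
        with pytest.warns(UserWarning, match="all-missing"):
            res = pca_project(G, 1)
        assert res.kept_markers == ["m1"]


class TestGenotypeIo:
    def test_round_trip(self):
        spec, (G, _, panel) = small_panel(n_study=5, ref=(3, 3, 3))
        buf = io.StringIO()
        write_genotype_table(G, buf)
        buf.seek(0)
        back = read_genotype_table(buf)
        assert back.individuals == G.individuals
        assert back.labels == G.labels
        assert np.array_equal(back.dosages, G.dosages)

    def test_na_handling(self):
        buf = io.StringIO("individual\tgroup\tm1\tm2\n"
                          "s1\tstudy\t1\tNA\n")
        G = read_genotype_table(buf)
        assert G.dosages[0, 0] == 1.0 and np.isnan(G.dosages[0, 1])

    def test_bad_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosages"):
            GenotypeMatrix(["a"], ["g"], ["m"], np.array([[3.0]]))

    def test_vcf_ingestion_gt_to_dosage(self, tmp_path):
        vcf = tmp_path / "aims.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
            "\tS1\tS2\n"
            "1\t100\trs1\tA\tAT\t.\t.\t.\tGT\t0/1\t1/1\n"
            "1\t200\trs2\tGC\tG\t.\t.\t.\tGT\t0/0\t./.\n"
            "1\t300\trs3\tC\tCT,CTT\t.\t.\t.\tGT\t0/2\t0/1\n")
        G = ancestry.read_genotype_vcf(str(vcf),
                                       group_map={"S1": "AFR"})
        assert G.individuals == ["S1", "S2"]
        assert G.labels == ["AFR", "study"]
        assert G.markers == ["rs1", "rs2", "rs3"]
        assert G.dosages[0, 0] == 1.0 and G.dosages[1, 0] == 2.0
        assert G.dosages[0, 1] == 0.0 and np.isnan(G.dosages[1, 1])
        # third allelic state: recorded as missing for the dosage model
        assert np.isnan(G.dosages[0, 2]) and G.dosages[1, 2] == 1.0
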