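"""PCA fitting against an independent eigendecomposition oracle, separating-
component selection, extreme-loading pre-selection and greedy pruning."""

import numpy as np
import pandas as pd
import pytest

from metasig.data_model import ExpressionMatrix, Scale, standardize_genes
from metasig.intersect import GeneList
from metasig.signature import (
    PruneConfig,
    discover_signature,
    greedy_prune,
    pca_fit,
    select_extreme_loadings,
    select_separating_component,
    separation_statistic,
)
from metasig import stats_core


def std_matrix(arr, genes=None, samples=None):
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    m = ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), Scale.RAW_LOG2)
    return standardize_genes(m)


class TestPCAFit:
    def test_perfect_anticorrelation_is_rank_one(self):
        g1 = np.array([1.0, 2.0, 3.0, 4.0])
        m = std_matrix(np.vstack([g1, -g1]))
        model = pca_fit(m)
        np.testing.assert_allclose(model.variance_explained, [1.0, 0.0], atol=1e-12)

    def test_variance_fractions_sum_to_one_and_ordered(self):
        rng = np.random.default_rng(14)
        model = pca_fit(std_matrix(rng.normal(size=(12, 20))))
        assert model.variance_explained.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(model.variance_explained) <= 1e-12).all()

    def test_loadings_orthonormal_and_orientation(self):
        rng = np.random.default_rng(15)
        model = pca_fit(std_matrix(rng.normal(size=(8, 25))))
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        for k in range(model.loadings.shape[1]):
            j = np.argmax(np.abs(model.loadings[:, k]))
            assert model.loadings[j, k] > 0

    def test_matches_covariance_eigendecomposition_oracle(self):
        # independent oracle: full eigendecomposition of the gene-gene covariance
        rng = np.random.default_rng(16)
        m = std_matrix(rng.normal(size=(20, 30)))
        model = pca_fit(m)
        x = m.values.to_numpy().T
        x = x - x.mean(axis=0)
        cov = x.T @ x / (x.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            model.variance_explained, evals / evals.sum(), atol=1e-6
        )
        k_eff = min(x.shape) - 1  # centering removes one dimension
        for k in range(k_eff):
            v = evecs[:, k]
            w = model.loadings[:, k]
            assert abs(abs(v @ w) - 1.0) < 1e-6  # same axis up to sign

    def test_requires_standardized_matrix(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)))
        df.index = [f"g{i}" for i in range(3)]
        df.columns = [f"s{j}" for j in range(5)]
        with pytest.raises(ValueError, match="standardized"):
            pca_fit(ExpressionMatrix(df, Scale.RAW_LOG2))


class TestSeparation:
    def test_perfectly_split_scores_auc_one(self, make_ann):
        arr = np.array([[1.0, 1.1, 3.0, 3.1], [1.0, 1.2, 3.2, 3.0]])
        m = std_matrix(arr)
        ann = make_ann(["primary", "primary", "metastatic", "metastatic"])
        res = separation_statistic(pca_fit(m), ann, 0)
        assert res.auc == pytest.approx(1.0)

    def test_statistic_equals_direct_welch_on_scores(self, make_ann):
        rng = np.random.default_rng(17)
        m = std_matrix(rng.normal(size=(6, 20)))
        ann = make_ann(["primary"] * 11 + ["metastatic"] * 9)
        model = pca_fit(m)
        res = separation_statistic(model, ann, 0)
        scores = model.scores[:, 0]
        direct = stats_core.welch_t(scores[:11], scores[11:])
        assert res.statistic == pytest.approx(abs(direct.statistic))

    def test_signal_on_second_component_found(self, make_ann):
        # a strong class-blind nuisance factor owns PC1; the class shift
        # lives on PC2 and must still be discovered with k_max=3
        rng = np.random.default_rng(18)
        n = 60
        classes = ["primary"] * 30 + ["metastatic"] * 30
        shift = np.array([0.0] * 30 + [2.0] * 30)
        nuisance = rng.normal(0, 3, n)
        rows = [nuisance + rng.normal(0, 0.5, n) for _ in range(6)]
        rows += [shift + rng.normal(0, 1, n) for _ in range(4)]
        m = std_matrix(np.vstack(rows))
        ann = make_ann(classes)
        model = pca_fit(m)
        res = select_separating_component(model, ann, k_max=3)
        assert res.component_index == 1

    def test_k_max_one_returns_first_component(self, make_ann):
        rng = np.random.default_rng(19)
        m = std_matrix(rng.normal(size=(5, 16)))
        ann = make_ann(["primary"] * 8 + ["metastatic"] * 8)
        assert select_separating_component(pca_fit(m), ann, k_max=1).component_index == 0


class TestExtremeLoadings:
    def fixed_model(self):
        arr = np.vstack(
            [
                np.array([1.0, 2, 3, 4, 5, 6]),
                -np.array([1.0, 2, 3, 4, 5, 6.2]),
                np.random.default_rng(1).normal(0, 0.1, 6),
            ]
        )
        return pca_fit(std_matrix(arr, genes=["gA", "gB", "gC"]))

    def test_largest_absolute_loadings_selected(self):
        model = self.fixed_model()
        gl = select_extreme_loadings(model, 0, 2)
        assert gl.genes == frozenset({"GA", "GB"})

    def test_k_equals_all_is_identity(self):
        model = self.fixed_model()
        gl = select_extreme_loadings(model, 0, 3)
        assert gl.genes == frozenset({"GA", "GB", "GC"})

    def test_tie_breaks_lexicographic(self, make_ann):
        # two identical genes tie exactly in |loading|; with k=1 the
        # lexicographically smaller id wins
        g = np.array([1.0, 2, 3, 4])
        m = std_matrix(np.vstack([g, g]), genes=["gB", "gA"])
        model = pca_fit(m)
        assert abs(model.loadings[0, 0]) == pytest.approx(abs(model.loadings[1, 0]))
        gl = select_extreme_loadings(model, 0, 1)
        assert gl.genes == frozenset({"GA"})

    def test_k_out_of_range(self):
        model = self.fixed_model()
        with pytest.raises(ValueError):
            select_extreme_loadings(model, 0, 0)
        with pytest.raises(ValueError):
            select_extreme_loadings(model, 0, 4)


class TestGreedyPrune:
    def test_redundant_copies_collapse(self, make_ann):
        # three exact copies of one class indicator: PC1 explains everything,
        # pruning may only shed the redundant copies
        indicator = np.array([0.0] * 10 + [1.0] * 10)
        m = std_matrix(np.vstack([indicator] * 3), genes=["c1", "c2", "c3"])
        ann = make_ann(["primary"] * 10 + ["metastatic"] * 10)
        sig, trace = greedy_prune(m, ann, ["c1", "c2", "c3"], PruneConfig(min_size=2))
        assert len(sig.genes) == 2
        assert sig.final_variance_explained == pytest.approx(1.0)
        for step in trace.accepted():
            assert step.variance_explained_0 == pytest.approx(1.0)

    def test_accepted_steps_never_reduce_first_component_value(self, hotpam_study):
        std = standardize_genes(hotpam_study.expression)
        _, trace = greedy_prune(
            std, hotpam_study.annotation, hotpam_study.signature_panel(), PruneConfig()
        )
        accepted_ve = [s.variance_explained_0 for s in trace.accepted()]
        assert all(b >= a - 1e-6 for a, b in zip(accepted_ve, accepted_ve[1:]))

    def test_panel_below_min_size_rejected(self, hotpam_study):
        std = standardize_genes(hotpam_study.expression)
        with pytest.raises(ValueError, match="min_size"):
            greedy_prune(std, hotpam_study.annotation, ["KIN1"], PruneConfig(min_size=2))

    def test_recovers_planted_genes(self, hotpam_study):
        std = standardize_genes(hotpam_study.expression)
        planted = set(hotpam_study.planted_genes()) - {"DRIVER1"}
        sig, _ = greedy_prune(
            std, hotpam_study.annotation, hotpam_study.signature_panel(), PruneConfig()
        )
        got = set(sig.genes)
        assert len(got & planted) >= 6
        assert len(got - planted) <= 3


class TestDiscoverSignature:
    def test_deterministic_rerun(self, hotpam_study):
        std = standardize_genes(hotpam_study.expression)
        panel = GeneList.from_iterable("panel", hotpam_study.signature_panel())
        sig1, _ = discover_signature(std, hotpam_study.annotation, panel)
        sig2, _ = discover_signature(std, hotpam_study.annotation, panel)
        assert sig1.genes == sig2.genes
        assert sig1.final_variance_explained == sig2.final_variance_explained

    def test_permutation_equivariance(self, hotpam_study):
        std = standardize_genes(hotpam_study.expression)
        panel = hotpam_study.signature_panel()
        sig1, _ = discover_signature(std, hotpam_study.annotation, panel)
        rng = np.random.default_rng(23)
        shuffled_rows = list(rng.permutation(std.gene_ids))
        std_perm = ExpressionMatrix(std.values.loc[shuffled_rows], Scale.GENE_STANDARDIZED)
        sig2, _ = discover_signature(std_perm, hotpam_study.annotation, panel)
        assert set(sig1.genes) == set(sig2.genes)

    def test_null_panel_gives_chance_level_separation_out_of_sample(self, make_ann):
        # no informative genes: the discovered signature may look mildly
        # separating in-sample (selection bias) but must collapse to chance
        # on an independent null cohort
        rng = np.random.default_rng(24)
        classes = ["primary"] * 100 + ["metastatic"] * 100
        m1 = std_matrix(rng.normal(size=(50, 200)))
        m2 = std_matrix(rng.normal(size=(50, 200)))
        ann = make_ann(classes)
        sig, _ = discover_signature(m1, ann, m1.gene_ids)
        assert sig.final_separation.auc < 0.7  # in-sample bias stays bounded
        model2 = pca_fit(m2.subset_genes(list(sig.genes)))
        transfer = separation_statistic(model2, ann, 0)
        assert transfer.auc == pytest.approx(0.5, abs=0.1)
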