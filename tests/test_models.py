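import numpy as np
import pandas as pd
import pytest

from nodalrad.errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    DegenerateLabelError,
)
from nodalrad.models import (
    FeatureSetSpec,
    HyperparameterConfig,
    assemble_feature_set,
    fit_model,
    fit_pca,
    fit_pipeline,
    sample_hyperparameters,
)


def _tables(n=6):
    idx = [f"N{i}" for i in range(n)]
    rng = np.random.default_rng(0)
    hand = pd.DataFrame(
        rng.normal(size=(n, 4)),
        index=idx,
        columns=["firstorder.mean", "firstorder.variance", "shape.volume_mm3",
                 "glcm.contrast"],
    )
    deep = pd.DataFrame(rng.normal(size=(n, 3)), index=idx,
                        columns=["deep.s3.c000", "deep.s3.c001", "deep.s3.c002"])
    return hand, deep


class TestFeatureSets:
    def test_hybrid_excludes_higher_order_handcrafted(self):
        hand, deep = _tables()
        out = assemble_feature_set(hand, deep, FeatureSetSpec("hybrid"))
        assert not any(c.startswith("glcm.") for c in out.columns)
        assert any(c.startswith("deep.") for c in out.columns)

    def test_handcrafted_excludes_deep(self):
        hand, deep = _tables()
        out = assemble_feature_set(hand, deep, FeatureSetSpec("handcrafted"))
        assert not any(c.startswith("deep.") for c in out.columns)

    def test_hybrid_column_count(self):
        hand, deep = _tables()
        out = assemble_feature_set(hand, deep, FeatureSetSpec("hybrid"))
        n_fo = sum(c.startswith("firstorder.") for c in hand.columns)
        n_sh = sum(c.startswith("shape.") for c in hand.columns)
        assert out.shape[1] == n_fo + n_sh + deep.shape[1]

    def test_misaligned_tables_rejected(self):
        hand, deep = _tables()
        with pytest.raises(AlignmentError):
            assemble_feature_set(hand, deep.iloc[::-1], FeatureSetSpec("hybrid"))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            FeatureSetSpec("everything")


class TestPca:
    def test_rank_two_data_needs_two_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2)) @ rng.normal(size=(2, 9))
        t = fit_pca(X - X.mean(0), variance_threshold=0.95)
        assert t.n_components == 2

    def test_iid_equal_variance_needs_all_components(self):
        X = np.random.default_rng(2).normal(size=(3000, 10))
        assert fit_pca(X, 0.95).n_components == 10

    def test_threshold_one_keeps_full_rank(self):
        X = np.random.default_rng(3).normal(size=(50, 7))
        assert fit_pca(X, 1.0).n_components == 7

    def test_components_orthonormal(self):
        X = np.random.default_rng(4).normal(size=(100, 6))
        t = fit_pca(X, 0.95)
        np.testing.assert_allclose(t.components @ t.components.T,
                                   np.eye(t.n_components), atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_pca(np.ones((10, 3)), 0.95)


class TestFitModel:
    def test_extreme_penalty_predicts_train_prevalence(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = (rng.random(60) < 0.25).astype(int)
        hp = HyperparameterConfig(model="elastic_logit", penalty_strength=1e8)
        probs = fit_model(X, y, hp).predict_probability(X)
        np.testing.assert_allclose(probs, y.mean(), atol=0.01)

    def test_separable_data_perfect_training_auc(self):
        from nodalrad.evaluation import auc

        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        hp = HyperparameterConfig(model="elastic_logit", penalty_strength=0.01)
        assert auc(y, fit_model(X, y, hp).predict_probability(X)) == 1.0

    @pytest.mark.parametrize("model", ["elastic_logit", "random_forest"])
    def test_deterministic_given_seed(self, model):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] + rng.normal(size=80) > 0).astype(int)
        hp = HyperparameterConfig(model=model, n_trees=50)
        p1 = fit_model(X, y, hp, seed=3).predict_probability(X)
        p2 = fit_model(X, y, hp, seed=3).predict_probability(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_labels_rejected(self):
        with pytest.raises(DegenerateLabelError):
            fit_model(np.zeros((5, 2)), np.zeros(5), HyperparameterConfig())

    def test_elastic_l1_share_sparsifies_coefficients(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(150, 10))
        y = (X[:, 0] - X[:, 1] + rng.normal(scale=0.5, size=150) > 0).astype(int)
        counts = []
        for l1 in (0.0, 0.5, 1.0):
            hp = HyperparameterConfig(model="elastic_logit", penalty_strength=20.0,
                                      l1_ratio=l1)
            m = fit_model(X, y, hp)
            counts.append(int((np.abs(m._est.coef_) > 1e-8).sum()))
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[2] < counts[0]  # pure L1 actually zeroes noise features


class TestHyperparameterSampling:
    def test_count_and_distinct_ids(self):
        cfgs = sample_hyperparameters(None, 50, 3)
        assert len(cfgs) == 50
        assert len({c.config_id for c in cfgs}) == 50

    def test_bounded_fields_within_bounds(self):
        for c in sample_hyperparameters(None, 100, 4):
            assert 0.0 <= c.l1_ratio <= 1.0
            assert 1e-2 <= c.penalty_strength <= 1e2
            assert 100 <= c.n_trees <= 1000
            assert c.depth_k in (1, 2, 3, 4)

    def test_reproducible_from_seed(self):
        assert sample_hyperparameters(None, 20, 9) == sample_hyperparameters(None, 20, 9)

    def test_model_restriction(self):
        cfgs = sample_hyperparameters(None, 10, 1, models=("elastic_logit",))
        assert all(c.model == "elastic_logit" for c in cfgs)

    def test_empty_space_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_hyperparameters(None, 0, 1)


class TestPipelineFit:
    def test_pipeline_statistics_from_training_rows_only(self):
        rng = np.random.default_rng(8)
        Xtr = rng.normal(loc=0.0, size=(100, 5))
        y = (Xtr[:, 0] > 0).astype(int)
        hp = HyperparameterConfig(model="elastic_logit", use_pca=True)
        pipe = fit_pipeline(Xtr, y, hp, seed=0)
        np.testing.assert_allclose(pipe.scaler.mean_, Xtr.mean(axis=0))
        # transforming shifted test data must use the train center
        Xte = rng.normal(loc=5.0, size=(10, 5))
        probs = pipe.predict_probability(Xte)
        assert np.all((probs >= 0) & (probs <= 1))
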