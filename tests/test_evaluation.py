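import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodalrad.errors import ConfigurationError, UndefinedMetricError
from nodalrad.evaluation import (
    PredictionMatrix,
    auc,
    bbc_select,
    brier,
    cross_validate,
    lowess_calibration,
    make_patient_folds,
    naive_pooled_best,
    naive_reference,
    paired_bootstrap_z_test,
    patient_positivity_strata,
    scaled_brier,
    youden_cutoff,
)
from nodalrad.models import HyperparameterConfig


def brute_force_auc(y, p):
    """Pairwise-count oracle for the Mann-Whitney AUC."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


class TestFoldPlan:
    def test_hundred_patients_twenty_folds_five_each(self):
        pats = [f"P{i}" for i in range(100)]
        plan = make_patient_folds(pats, folds=20, repeats=1, seed=0)
        sizes = [len(f) for f in plan.assignment[0]]
        assert sizes == [5] * 20

    def test_partition_property(self):
        pats = [f"P{i}" for i in range(37)]
        plan = make_patient_folds(pats, folds=5, repeats=3, seed=1)
        for r in range(3):
            seen = [p for f in plan.assignment[r] for p in f]
            assert sorted(seen) == sorted(pats)

    def test_repeats_times_folds_test_sets(self):
        plan = make_patient_folds([f"P{i}" for i in range(40)], 20, 10, 0)
        assert sum(len(r) for r in plan.assignment) == 200

    def test_more_folds_than_patients_rejected(self):
        with pytest.raises(ConfigurationError):
            make_patient_folds(["A", "B"], folds=3, repeats=1, seed=0)

    def test_stratification_balances_positivity(self):
        pats = [f"P{i}" for i in range(40)]
        strata = {p: (1 if i < 20 else 0) for i, p in enumerate(pats)}
        plan = make_patient_folds(pats, folds=4, repeats=2, seed=2, strata=strata)
        for fold in plan.assignment[0]:
            assert sum(strata[p] for p in fold) == 5  # 20 positives over 4 folds


class TestAuc:
    def test_perfect_ordering(self):
        assert auc(np.array([1, 0]), np.array([0.9, 0.1])) == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.array([1, 0, 1, 0]), np.full(4, 0.3)) == 0.5

    def test_enumerated_three_points(self):
        assert auc(np.array([1, 0, 0]), np.array([0.4, 0.8, 0.1])) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc(np.ones(4), np.random.default_rng(0).random(4))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_pairwise_count(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 200)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        p = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        assert auc(y, p) == pytest.approx(brute_force_auc(y, p), abs=1e-12)


class TestBrierAndScaled:
    def test_hand_computed_brier(self):
        assert brier(np.array([1, 0]), np.array([0.8, 0.3])) == pytest.approx(0.065)

    def test_constant_prediction_closed_form(self):
        y = np.array([1, 0, 0, 0, 1])
        pi = y.mean()
        assert brier(y, np.full(5, pi)) == pytest.approx(pi * (1 - pi))

    def test_scaled_brier_arithmetic(self):
        ref = naive_reference(np.array([1, 0, 1, 0]), 0.5)
        y = np.array([1, 0, 1, 0])
        assert scaled_brier(y, y.astype(float), ref) == 100.0
        assert scaled_brier(y, np.full(4, 0.5), ref) == 0.0

    def test_half_error_reduction_is_fifty_percent(self):
        # BS = 0.08 against BS_ref = 0.16
        from nodalrad.evaluation import NaiveReference

        y = np.array([0.0, 0.0])
        probs = np.array([0.2, 0.2])  # BS = 0.04... construct directly instead
        ref = NaiveReference(bs_ref=0.16)
        probs = np.array([np.sqrt(0.08), np.sqrt(0.08)])
        assert scaled_brier(y, probs, ref) == pytest.approx(50.0)


class TestYouden:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        cut, sens, spec = youden_cutoff(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert (sens, spec) == (1.0, 1.0)
        assert 0.2 < cut <= 0.8

    def test_enumerated_max_j(self):
        y = np.array([1, 0, 1, 0])
        cut, sens, spec = youden_cutoff(y, np.array([0.9, 0.8, 0.7, 0.1]))
        assert sens + spec - 1.0 == pytest.approx(0.5)
        assert cut == pytest.approx(0.4)  # smallest maximizer (favours sensitivity)

    def test_uninformative_predictions(self):
        y = np.array([1, 0, 1, 0])
        _, sens, spec = youden_cutoff(y, np.full(4, 0.5))
        assert sens + spec - 1.0 == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p = np.round(rng.random(50), 2)
        cut, sens, spec = youden_cutoff(y, p)
        best = max(
            ((p >= t) & (y == 1)).sum() / y.sum()
            + ((p < t) & (y == 0)).sum() / (1 - y).sum()
            for t in np.linspace(-0.01, 1.01, 1000)
        )
        assert sens + spec == pytest.approx(best, abs=1e-9)


class TestLowessCalibration:
    def test_well_calibrated_predictions_track_diagonal(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 5000)
        y = (rng.random(5000) < p).astype(int)
        curve = lowess_calibration(y, p)
        assert np.max(np.abs(curve[:, 1] - curve[:, 0])) < 0.05

    def test_constant_predictions_single_point(self):
        y = np.random.default_rng(1).integers(0, 2, 30)
        curve = lowess_calibration(y, np.full(30, 0.4))
        assert curve.shape == (1, 2)
        assert curve[0, 0] == pytest.approx(0.4)
        assert curve[0, 1] == pytest.approx(y.mean())

    def test_row_order_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        y = (rng.random(200) < p).astype(int)
        perm = rng.permutation(200)
        np.testing.assert_allclose(
            lowess_calibration(y, p), lowess_calibration(y[perm], p[perm])
        )

    def test_too_few_rows_rejected(self):
        with pytest.raises(ConfigurationError):
            lowess_calibration(np.array([0, 1] * 5), np.linspace(0, 1, 10))


class TestPairedBootstrapZ:
    def test_identical_predictions_give_p_one(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 40)
        p = rng.random(80)
        res = paired_bootstrap_z_test(y, p, p, metric="auc", B=500, seed=1)
        assert res.p == 1.0
        assert res.difference == 0.0

    def test_perfect_vs_random_strongly_significant(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 500)
        y[:2] = [0, 1]
        perfect = y.astype(float) * 0.8 + 0.1
        random = rng.random(500)
        res = paired_bootstrap_z_test(y, perfect, random, metric="auc", B=500, seed=2)
        assert res.p < 0.001
        assert res.difference > 0

    def test_type_i_error_rate_near_nominal(self):
        # two independent uninformative predictors; rejection rate at
        # alpha=0.05 should be near nominal across null simulations
        rng = np.random.default_rng(7)
        n, sims = 150, 200
        rejections = 0
        for s in range(sims):
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            pa, pb = rng.random(n), rng.random(n)
            res = paired_bootstrap_z_test(y, pa, pb, metric="auc", B=300, seed=s)
            rejections += res.p < 0.05
        assert 0.02 <= rejections / sims <= 0.09


def _matrix_from(probs_3d, labels, train_prev=None):
    R, N, C = probs_3d.shape
    if train_prev is None:
        train_prev = np.full((R, N), labels.mean())
    return PredictionMatrix(
        probs=probs_3d,
        train_prev=train_prev,
        node_ids=[f"N{i}" for i in range(N)],
        config_ids=[f"cfg{c:03d}" for c in range(C)],
        labels=labels,
    )


class TestBbcSelect:
    def test_single_config_matches_plain_pooled_estimate(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        p = np.clip(0.25 * y + 0.2 + 0.5 * rng.random(300), 0, 1)
        M = _matrix_from(p.reshape(1, 300, 1), y)
        res = bbc_select(M, selection_metric="auc", B=300, seed=0,
                         eval_metrics=("auc",))
        plain = auc(y, p)
        half_width = (res.ci["auc"][1] - res.ci["auc"][0]) / 2
        assert abs(res.corrected["auc"] - plain) < half_width

    def test_null_configs_optimism_removed(self):
        # many uninformative configs: picking the best on pooled data is
        # optimistic; BBC must bring the estimate back to chance level
        rng = np.random.default_rng(6)
        N, C = 400, 50
        y = (rng.random(N) < 0.3).astype(int)
        probs = rng.random((1, N, C))
        M = _matrix_from(probs, y)
        naive, _ = naive_pooled_best(M, "auc")
        res = bbc_select(M, selection_metric="auc", B=500, seed=1,
                         eval_metrics=("auc",))
        assert naive > 0.5
        assert abs(res.corrected["auc"] - 0.5) < 0.05
        assert res.corrected["auc"] < naive

    def test_dominant_config_selected_almost_always(self):
        rng = np.random.default_rng(7)
        N = 300
        y = (rng.random(N) < 0.3).astype(int)
        y[:2] = [0, 1]
        good = np.clip(0.65 * y + 0.2 + 0.1 * rng.random(N), 0, 1)
        bad = rng.random((N, 3))
        probs = np.concatenate([good[:, None], bad], axis=1)[None, :, :]
        M = _matrix_from(probs, y)
        res = bbc_select(M, selection_metric="auc", B=200, seed=2)
        assert res.selection_frequencies["cfg000"] > 0.95

    def test_selection_frequencies_sum_to_one(self):
        rng = np.random.default_rng(8)
        y = (rng.random(100) < 0.4).astype(int)
        y[:2] = [0, 1]
        M = _matrix_from(rng.random((2, 100, 4)), y)
        res = bbc_select(M, B=100, seed=3)
        assert sum(res.selection_frequencies.values()) == pytest.approx(1.0)


class TestCrossValidate:
    @pytest.fixture
    def toy_problem(self):
        rng = np.random.default_rng(9)
        n_pat = 12
        pid = [f"P{i:02d}" for i in range(n_pat) for _ in range(8)]
        n = len(pid)
        signal = rng.normal(size=n)
        y = (signal + 0.8 * rng.normal(size=n) > 0.5).astype(int)
        X = pd.DataFrame({
            "firstorder.signal": signal,
            "firstorder.noise1": rng.normal(size=n),
            "firstorder.noise2": rng.normal(size=n),
        }, index=[f"N{i}" for i in range(n)])
        return X, y, pid

    def test_patient_exclusivity_and_shape(self, toy_problem):
        X, y, pid = toy_problem
        strata = patient_positivity_strata(pid, y)
        plan = make_patient_folds(sorted(set(pid)), 4, 2, 0, strata)
        cfgs = [HyperparameterConfig(model="elastic_logit", config_id="cfg000"),
                HyperparameterConfig(model="elastic_logit", penalty_strength=5.0,
                                     config_id="cfg001")]
        M = cross_validate(X, y, pid, cfgs, plan, seed=0)
        assert M.probs.shape == (2, len(y), 2)
        assert np.all((M.probs >= 0) & (M.probs <= 1))

    def test_planted_label_feature_reaches_perfect_auc(self, toy_problem):
        X, y, pid = toy_problem
        X = X.copy()
        X["firstorder.leak"] = y.astype(float)
        strata = patient_positivity_strata(pid, y)
        plan = make_patient_folds(sorted(set(pid)), 4, 1, 0, strata)
        cfgs = [HyperparameterConfig(model="elastic_logit", penalty_strength=0.01,
                                     use_pca=False)]
        M = cross_validate(X, y, pid, cfgs, plan, seed=0)
        assert auc(y, M.probs[0, :, 0]) > 0.95
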