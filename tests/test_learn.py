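"""Learning harness: RFE ranking, classifiers, metrics, CV integrity."""

import numpy as np
import pytest
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from edascreen.learn import (
    CLASSIFIERS,
    ModelConfig,
    SVMRFE,
    compute_metrics,
    encode_labels,
    rank_auc,
    repeated_cv,
    roc_points,
    standardize_fit_apply,
    train_predict,
)


class TestStandardize:
    def test_scaling_arithmetic(self):
        train = np.array([[3.0], [5.0], [7.0]])  # mean 5, sd 2 (population)
        _, ev, _ = standardize_fit_apply(train, np.array([[7.0]]))
        sd = train.std()
        assert ev[0, 0] == pytest.approx((7.0 - 5.0) / sd)

    def test_constant_column_maps_to_zero(self):
        train = np.column_stack([np.ones(5), np.arange(5.0)])
        tr, _, (mean, sd) = standardize_fit_apply(train, train)
        np.testing.assert_allclose(tr[:, 0], 0.0)
        assert sd[0] == 1.0

    def test_reapplying_scaler_normalises_train(self):
        rng = np.random.default_rng(0)
        train = rng.normal(5, 3, size=(50, 4))
        tr, _, _ = standardize_fit_apply(train, train)
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tr.std(axis=0), 1.0, atol=1e-9)


class TestSVMRFE:
    def test_single_feature_rank_one(self):
        X = np.random.default_rng(0).normal(size=(20, 1))
        y = (X[:, 0] > 0).astype(int)
        assert SVMRFE().fit(X, y).ranking_.tolist() == [1]

    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 12))
        y = rng.integers(0, 2, 30)
        r = SVMRFE().fit(X, y).ranking_
        assert sorted(r) == list(range(1, 13))

    def test_informative_feature_ranked_first(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 10))
            y = rng.integers(0, 2, 100)
            X[:, 0] += 5.0 * y  # feature 0 separates at 5 SD
            if SVMRFE().fit(X, y).ranking_[0] == 1:
                hits += 1
        assert hits >= 95

    def test_matches_sklearn_rfe(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 8))
        y = rng.integers(0, 2, 40)
        mine = SVMRFE(C=1.0).fit(X, y).ranking_
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=1).fit(X, y)
        np.testing.assert_array_equal(mine, ref.ranking_)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            SVMRFE().fit(np.zeros((5, 3)), np.zeros(5))

    def test_top_features_best_first(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 6))
        y = rng.integers(0, 2, 60)
        X[:, 4] += 4.0 * y
        rfe = SVMRFE().fit(X, y)
        top = rfe.top_features(3)
        assert top[0] == 4
        assert rfe.ranking_[top].tolist() == [1, 2, 3]


class TestTrainPredict:
    @staticmethod
    def _blobs(seed=0, n=20, sep=8.0):
        rng = np.random.default_rng(seed)
        X = np.r_[rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))]
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        return X, y

    @pytest.mark.parametrize("kind", ["svm", "tree"])
    def test_separable_blobs_fit_perfectly(self, kind):
        X, y = self._blobs()
        pred, _ = train_predict(kind, X, y, X)
        assert (pred == y).all()

    def test_knn_unanimous_neighbours(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0]])
        y = np.array([1, 1, 1, 0])
        pred, score = train_predict("knn", X, y, np.array([[0.05]]))
        assert pred[0] == 1 and score[0] == pytest.approx(1.0)

    def test_nb_symmetric_boundary_at_midpoint(self):
        rng = np.random.default_rng(4)
        X = np.r_[rng.normal(-2, 1, (200, 1)), rng.normal(2, 1, (200, 1))]
        y = np.r_[np.zeros(200, int), np.ones(200, int)]
        grid = np.linspace(-1.5, 1.5, 61)[:, None]
        _, score = train_predict("nb", X, y, grid)
        crossings = np.nonzero(np.diff(score > 0.5))[0]
        assert len(crossings) == 1
        assert abs(grid[crossings[0], 0]) < 0.2  # boundary near the midpoint

    def test_dimension_mismatch_rejected(self):
        X, y = self._blobs()
        with pytest.raises(ValueError, match="features"):
            train_predict("svm", X, y, np.zeros((3, 5)))

    def test_svm_margin_oriented_toward_case(self):
        X, y = self._blobs()
        _, score = train_predict("svm", X, y, X)
        assert score[y == 1].mean() > score[y == 0].mean()


class TestMetrics:
    def test_hand_computed_confusion_rates(self):
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 1])  # TP3 FN1 TN4 FP2
        m = compute_metrics(pred, pred.astype(float), truth)
        assert m["sensitivity"] == pytest.approx(75.0)
        assert m["specificity"] == pytest.approx(400 / 6, abs=0.01)
        assert m["ppv"] == pytest.approx(60.0)
        assert m["npv"] == pytest.approx(80.0)
        assert m["accuracy"] == pytest.approx(70.0)

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 0, 1])
        m = compute_metrics(truth, truth.astype(float), truth)
        assert m["accuracy"] == 100.0 and m["auc"] == 1.0

    def test_constant_scores_auc_half(self):
        truth = np.array([0, 1, 0, 1, 1])
        assert rank_auc(np.ones(5), truth) == pytest.approx(0.5)

    def test_one_class_truth_auc_missing(self):
        m = compute_metrics(np.ones(3), np.ones(3), np.ones(3))
        assert m["auc"] is None

    def test_rank_auc_equals_trapezoidal_roc_area(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)  # tie-free
        truth = rng.integers(0, 2, 200)
        mine = rank_auc(scores, truth)
        pts = roc_points(scores, truth)
        trap = np.trapezoid(pts["tpr"], pts["fpr"])
        assert mine == pytest.approx(trap, abs=1e-9)
        assert mine == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_metrics_invariant_to_sample_order(self):
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 2, 40)
        pred = rng.integers(0, 2, 40)
        scores = rng.normal(size=40)
        perm = rng.permutation(40)
        a = compute_metrics(pred, scores, truth)
        b = compute_metrics(pred[perm], scores[perm], truth[perm])
        assert a == b


class TestRepeatedCV:
    def test_ranking_count_and_rank_table_bounds(self, feature_table_factory):
        table = feature_table_factory(n_per_group=15, informative={2: 2.0}, seed=4)
        cfg = ModelConfig(cv_repeats=2, subset_sizes=(1, 36), rng_seed=0)
        report, ranks = repeated_cv(table, cfg)
        assert report.n_rankings == 2 * 5
        assert ranks["average_rank"].between(1, 36).all()
        assert set(report.metrics["classifier"]) == set(CLASSIFIERS)

    def test_label_sentinel_reaches_near_perfect_accuracy(self, feature_table_factory):
        table = feature_table_factory(n_per_group=20, seed=5)
        # a feature equal to the label: genuine signal the ranking must find
        table["P1_MSCL"] = encode_labels(table["group"].to_numpy()).astype(float)
        cfg = ModelConfig(cv_repeats=2, subset_sizes=(1,), rng_seed=1)
        report, ranks = repeated_cv(table, cfg)
        assert ranks.iloc[0]["feature"] == "P1_MSCL"
        assert (report.metrics["accuracy"] > 95).all()

    def test_reproducible_given_seed(self, feature_table_factory):
        table = feature_table_factory(n_per_group=10, informative={1: 1.5}, seed=6)
        cfg = ModelConfig(cv_repeats=2, subset_sizes=(5,), rng_seed=7)
        r1, k1 = repeated_cv(table, cfg)
        r2, k2 = repeated_cv(table, cfg)
        assert r1.metrics.equals(r2.metrics)
        assert k1.equals(k2)

    def test_too_few_subjects_per_class_rejected(self, feature_table_factory):
        table = feature_table_factory(n_per_group=3, seed=7)
        with pytest.raises(ValueError, match="per class"):
            repeated_cv(table, ModelConfig(cv_folds=5))

    def test_subset_size_one_row_per_size(self, feature_table_factory):
        table = feature_table_factory(n_per_group=10, seed=8)
        cfg = ModelConfig(cv_repeats=1, subset_sizes=(11,), rng_seed=2)
        report, _ = repeated_cv(table, cfg)
        assert sorted(set(report.metrics["subset_size"])) == [11]
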