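import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnabindpred import (
    ConfusionCounts,
    CVPlan,
    GaussianNaiveBayes,
    confusion_from_labels,
    jackknife,
    make_folds,
    metrics,
    roc_auc,
    run_cv,
)

from conftest import gaussian_classification_data


class TestMetrics:
    def test_worked_example(self):
        m = metrics(ConfusionCounts(tp=40, tn=30, fp=20, fn=10))
        assert m["acc"] == pytest.approx(0.7)
        assert m["sen"] == pytest.approx(0.8)
        assert m["spe"] == pytest.approx(0.6)
        assert m["mcc"] == pytest.approx(0.40824829, abs=1e-7)

    def test_all_correct_gives_mcc_one(self):
        assert metrics(ConfusionCounts(10, 15, 0, 0))["mcc"] == 1.0

    def test_all_inverted_gives_mcc_minus_one(self):
        assert metrics(ConfusionCounts(0, 0, 15, 10))["mcc"] == -1.0

    def test_zero_denominator_convention(self):
        # everything predicted negative: TP+FP = 0
        assert metrics(ConfusionCounts(0, 5, 0, 5))["mcc"] == 0.0

    def test_empty_actual_class_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            metrics(ConfusionCounts(0, 5, 5, 0))
        with pytest.raises(ValueError, match="specificity"):
            metrics(ConfusionCounts(5, 0, 0, 5))
        with pytest.raises(ValueError, match="no evaluated"):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_bruteforce_confusion(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y_true = rng.integers(0, 2, size=n)
        y_pred = rng.integers(0, 2, size=n)
        if len(np.unique(y_true)) < 2:
            return
        counts = confusion_from_labels(y_true, y_pred)
        # independent naive loop
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)
        got = metrics(counts)
        assert got["acc"] == pytest.approx((tp + tn) / n)
        denom = np.sqrt(
            float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        )
        expected_mcc = (tp * tn - fp * fn) / denom if denom else 0.0
        assert got["mcc"] == pytest.approx(expected_mcc, abs=1e-12)


class TestFolds:
    def test_equal_division(self):
        plan = CVPlan(n_folds=5, seeds=(0,))
        folds = make_folds(10, plan, 0)
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_remainder_rule(self):
        plan = CVPlan(n_folds=5, seeds=(0,))
        folds = make_folds(11, plan, 0)
        assert sorted((len(f) for f in folds), reverse=True) == [3, 2, 2, 2, 2]

    def test_partition_property(self):
        plan = CVPlan(n_folds=4, seeds=(1, 2, 3))
        for r in range(3):
            folds = make_folds(23, plan, r)
            combined = np.concatenate(folds)
            assert len(combined) == 23
            assert len(np.unique(combined)) == 23

    def test_determinism(self):
        plan = CVPlan(n_folds=5, seeds=(42,))
        f1 = make_folds(30, plan, 0)
        f2 = make_folds(30, plan, 0)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_stratified_preserves_class_ratio(self):
        y = np.repeat([0, 1], [40, 20])
        plan = CVPlan(n_folds=4, seeds=(0,), stratified=True)
        for fold in make_folds(60, plan, 0, y=y):
            assert np.sum(y[fold] == 1) == 5
            assert np.sum(y[fold] == 0) == 10

    def test_too_few_samples(self):
        plan = CVPlan(n_folds=5, seeds=(0,))
        with pytest.raises(ValueError, match="cannot split"):
            make_folds(4, plan, 0)


class TestRunCV:
    def test_separable_data_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = gaussian_classification_data(rng, n_per_class=30, n_features=2,
                                            informative={0: 10.0})
        _, summary = run_cv(X, y, CVPlan.from_seed(0, n_runs=3))
        assert summary["mean_acc"] == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X, y = gaussian_classification_data(rng, n_per_class=100, n_features=5)
        per_run, summary = run_cv(X, y, CVPlan.from_seed(1, n_runs=10))
        assert abs(summary["mean_acc"] - 0.5) < 0.1
        assert len(per_run) == 10

    def test_accepts_sklearn_style_classifier(self):
        rng = np.random.default_rng(2)
        X, y = gaussian_classification_data(rng, n_per_class=30, n_features=2,
                                            informative={0: 6.0})
        _, fast = run_cv(X, y, CVPlan.from_seed(3, n_runs=2))
        _, est = run_cv(X, y, CVPlan.from_seed(3, n_runs=2),
                        classifier=GaussianNaiveBayes())
        assert fast == est

    def test_degenerate_training_split_named(self):
        X = np.arange(10, dtype=float)[:, None]
        y = np.array([1] + [0] * 9)  # the lone positive must land in some test fold
        with pytest.raises(ValueError, match="fold"):
            run_cv(X, y, CVPlan(n_folds=5, seeds=(0,)))


class TestJackknife:
    def test_separable_data(self):
        rng = np.random.default_rng(3)
        X, y = gaussian_classification_data(rng, n_per_class=10, n_features=2,
                                            informative={1: 10.0})
        assert jackknife(X, y)["acc"] == 1.0

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X, y = gaussian_classification_data(rng, n_per_class=12, n_features=3,
                                            informative={0: 1.0})
        assert jackknife(X, y) == jackknife(X, y)

    def test_minimum_size(self):
        with pytest.raises(ValueError, match="at least 3"):
            jackknife(np.zeros((2, 1)), [0, 1])


class TestROC:
    def test_perfect_ranking(self):
        curve = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert curve.auc == pytest.approx(1.0)

    def test_reversed_ranking(self):
        assert roc_auc([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9]).auc == pytest.approx(0.0)

    def test_curve_shape(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        curve = roc_auc(y, s)
        assert tuple(curve.points[0]) == (0.0, 0.0)
        assert tuple(curve.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 1000)
        s = rng.normal(size=1000)
        assert abs(roc_auc(y, s).auc - 0.5) < 0.05

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            return
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        auc = roc_auc(y, s).auc
        pos = s[y == 1]
        neg = s[y == 0]
        conc = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])
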