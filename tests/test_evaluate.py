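"""Two-stage evaluation protocol: splits, metrics, thresholds, importance."""

import numpy as np
import pytest

from tailsel import (
    FeatureTable,
    InvalidInputError,
    ModelSpec,
    UndefinedStatisticError,
    auc_bootstrap_ci,
    compute_metrics,
    permutation_importance,
    roc_auc,
    run_two_stage,
    select_threshold,
    stratified_split,
)

from conftest import brute_force_auc


def strong_table(rng, n=600, d=4):
    """One feature is a noisy copy of the label; the rest are noise."""
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, d))
    X[:, 0] = y + 0.4 * rng.standard_normal(n)
    return FeatureTable(X, [f"f{j}" for j in range(d)], y)


class TestStratifiedSplit:
    def test_per_class_counts(self, rng):
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        s = stratified_split(y, seed=0)
        assert y[s.test_idx].sum() == 6 and len(s.test_idx) == 20
        assert y[s.val_idx].sum() == 5 and len(s.val_idx) == 16

    def test_partition(self, rng):
        y = rng.integers(0, 2, 137)
        s = stratified_split(y, seed=5)
        pooled = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
        assert sorted(pooled) == list(range(137))
        assert len(set(pooled)) == 137

    def test_determinism(self, rng):
        y = rng.integers(0, 2, 80)
        a, b = stratified_split(y, seed=9), stratified_split(y, seed=9)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_small_class_rejected(self):
        with pytest.raises(InvalidInputError):
            stratified_split(np.array([0] * 20 + [1] * 3), seed=0)


class TestMetrics:
    def test_hand_worked_confusion(self):
        y_true = np.array([1, 1, 1, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 0, 1, 0, 0, 0])  # TP=2 TN=3 FP=1 FN=1
        acc, prec, rec, f1 = compute_metrics(y_true, y_pred)
        assert (acc, prec, rec, f1) == pytest.approx((5 / 7, 2 / 3, 2 / 3, 2 / 3))

    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 2, 30)
        assert compute_metrics(y, y) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_no_predicted_positives_convention(self):
        y = np.array([1, 0, 1])
        assert compute_metrics(y, np.zeros(3)) == pytest.approx((1 / 3, 0, 0, 0))

    def test_exhaustive_small_confusion_matrices(self):
        for tp in range(4):
            for tn in range(4):
                for fp in range(4):
                    for fn in range(4):
                        if tp + tn + fp + fn == 0:
                            continue
                        y_true = np.r_[
                            np.ones(tp + fn, int), np.zeros(tn + fp, int)
                        ]
                        y_pred = np.r_[
                            np.ones(tp, int), np.zeros(fn, int),
                            np.ones(fp, int), np.zeros(tn, int),
                        ]
                        acc, prec, rec, f1 = compute_metrics(y_true, y_pred)
                        assert acc == pytest.approx((tp + tn) / (tp + tn + fp + fn))
                        assert prec == pytest.approx(tp / (tp + fp) if tp + fp else 0)
                        assert rec == pytest.approx(tp / (tp + fn) if tp + fn else 0)


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_tie_gives_half(self):
        assert roc_auc([0, 1], [0.5, 0.5]) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 50)
        s = rng.standard_normal(50)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.exp(s)), abs=1e-12)

    def test_matches_pair_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.standard_normal(n), 1)  # force ties
            assert roc_auc(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            roc_auc([1, 1], [0.2, 0.4])


class TestAucBootstrap:
    def test_perfect_separation(self, rng):
        y = rng.integers(0, 2, 60)
        lo, hi = auc_bootstrap_ci(y, y.astype(float), B=100, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_containment_and_order(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 100))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.standard_normal(n) + 0.5 * y
            lo, hi = auc_bootstrap_ci(y, s, B=200, seed=1)
            point = roc_auc(y, s)
            assert lo <= hi
            assert lo - 0.05 <= point <= hi + 0.05

    def test_determinism(self, rng):
        y = rng.integers(0, 2, 40)
        s = rng.standard_normal(40)
        assert auc_bootstrap_ci(y, s, B=100, seed=4) == auc_bootstrap_ci(
            y, s, B=100, seed=4
        )


class TestSelectThreshold:
    def test_separable_case_picks_smallest_qualifying_cutoff(self):
        s = np.array([0.1, 0.2, 0.6, 0.9])
        y = np.array([0, 0, 1, 1])
        cut = select_threshold(s, y)
        assert 0.2 < cut <= 0.6
        _, _, _, f1 = compute_metrics(y, (s >= cut).astype(int))
        assert f1 == 1.0

    def test_beats_default_half_quantile(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        s = np.clip(0.3 * y + 0.2 + 0.2 * rng.random(n), 0, 1)
        cut = select_threshold(s, y)
        _, _, _, f_best = compute_metrics(y, (s >= cut).astype(int))
        _, _, _, f_half = compute_metrics(y, (s >= 0.5).astype(int))
        assert f_best >= f_half

    def test_constant_scores(self):
        s = np.full(10, 0.3)
        y = np.array([0, 1] * 5)
        cut = select_threshold(s, y)
        assert cut == pytest.approx(0.3)
        _, _, _, f1 = compute_metrics(y, (s >= cut).astype(int))
        _, _, _, f_all_pos = compute_metrics(y, np.ones(10, int))
        assert f1 == pytest.approx(f_all_pos)


class TestTwoStage:
    @pytest.mark.parametrize(
        "family", ["logistic", "random_forest", "gradient_boosting", "xgboost"]
    )
    def test_signal_recovery_across_families(self, rng, family):
        data = strong_table(rng)
        split = stratified_split(data.y, seed=11)
        run = run_two_stage(
            data, data.feature_names, ModelSpec(family, seed=0), split, B_auc=20
        )
        assert run.result.auc > 0.9
        assert 0.0 < run.result.threshold < 1.0

    def test_threshold_frozen_before_test_labels(self, rng):
        data = strong_table(rng)
        split = stratified_split(data.y, seed=3)
        spec = ModelSpec("logistic", seed=0)
        run = run_two_stage(data, data.feature_names, spec, split, B_auc=20)
        y2 = data.y.copy()
        y2[split.test_idx] = 1 - y2[split.test_idx]
        shuffled = FeatureTable(data.X, data.feature_names, y2)
        run2 = run_two_stage(shuffled, data.feature_names, spec, split, B_auc=20)
        assert run2.result.threshold == run.result.threshold
        assert run2.result.auc != pytest.approx(run.result.auc)

    def test_logistic_rescaling_invariance(self, rng):
        data = strong_table(rng, n=400)
        split = stratified_split(data.y, seed=8)
        spec = ModelSpec("logistic", seed=0)
        a = run_two_stage(data, data.feature_names, spec, split, B_auc=20)
        X2 = data.X.copy()
        X2[:, 0] *= 1000.0
        b = run_two_stage(
            FeatureTable(X2, data.feature_names, data.y),
            data.feature_names, spec, split, B_auc=20,
        )
        assert b.result.auc == pytest.approx(a.result.auc, abs=1e-6)
        assert b.result.f1 == pytest.approx(a.result.f1, abs=1e-6)

    def test_unknown_feature_rejected(self, rng):
        data = strong_table(rng, n=200)
        split = stratified_split(data.y, seed=1)
        with pytest.raises(InvalidInputError):
            run_two_stage(data, ["nope"], ModelSpec("logistic"), split)


class TestPermutationImportance:
    def test_constant_column_has_exactly_zero_drop(self, rng):
        data = strong_table(rng, n=300)
        X = data.X.copy()
        X[:, 2] = 5.0
        data = FeatureTable(X, data.feature_names, data.y)
        split = stratified_split(data.y, seed=2)
        run = run_two_stage(
            data, data.feature_names, ModelSpec("logistic", seed=0), split, B_auc=20
        )
        mean, _ = permutation_importance(
            run.model, run.X_test, run.y_test, n_repeats=20, seed=0
        )
        assert mean[2] == 0.0

    def test_informative_column_dominates(self, rng):
        data = strong_table(rng, n=500)
        split = stratified_split(data.y, seed=2)
        run = run_two_stage(
            data, data.feature_names, ModelSpec("logistic", seed=0), split, B_auc=20
        )
        mean, sd = permutation_importance(
            run.model, run.X_test, run.y_test, n_repeats=50, seed=0
        )
        assert mean[0] > 3 * sd[0]
        assert mean[0] == max(mean)
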