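"""SMOTE, logistic regression, scoring, CV and grid search."""

import numpy as np
import pytest

import sweatvoc as sv
from sweatvoc.core import ValidationError
from sweatvoc.modeling import LeakageError, _folds


class _FixedRng:
    """Deterministic stand-in driving SMOTE to a known interpolation point."""

    def __init__(self, u):
        self.u = u

    def integers(self, low, high, size=None):
        return np.zeros(size, dtype=int) if size is not None else 0

    def uniform(self, size=None):
        return np.full(size, self.u)


class TestSmote:
    def test_midpoint_interpolation(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0], [6.0, 6.0], [7.0, 7.0]])
        y = np.array([1, 1, 0, 0, 0])
        X_out, y_out, mask = sv.smote_oversample(X, y, k=1, rng=_FixedRng(0.5))
        assert mask.sum() == 1
        np.testing.assert_allclose(X_out[mask][0], [1.0, 1.0])

    def test_balances_study_sized_classes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(117, 6))
        y = np.array([1] * 74 + [0] * 43)
        _, y_out, mask = sv.smote_oversample(X, y, k=5, seed=1)
        values, counts = np.unique(y_out, return_counts=True)
        assert counts.tolist() == [74, 74]
        assert mask.sum() == 31

    def test_originals_unchanged_and_first(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        y = np.array([1] * 8 + [0] * 4)
        X_out, y_out, mask = sv.smote_oversample(X, y, k=2, seed=3)
        np.testing.assert_array_equal(X_out[:12], X)
        assert not mask[:12].any() and mask[12:].all()

    def test_synthetic_points_on_minority_segments(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 4))
        y = np.array([1] * 14 + [0] * 6)
        X_out, y_out, mask = sv.smote_oversample(X, y, k=3, seed=5)
        minority = X[y == 0]
        for s in X_out[mask]:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    u = (s - minority[i]) @ d / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        minority[i] + u * d, s, atol=1e-9
                    ):
                        on_segment = True
            assert on_segment

    def test_k_reduced_with_warning(self):
        X = np.arange(10.0).reshape(5, 2)
        y = np.array([1, 1, 1, 0, 0])
        with pytest.warns(UserWarning, match="reduced"):
            sv.smote_oversample(X, y, k=5, seed=0)

    def test_singleton_minority_rejected(self):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array([1, 1, 1, 0])
        with pytest.raises(ValidationError):
            sv.smote_oversample(X, y, k=1, seed=0)


class TestLogReg:
    def test_separable_data_fit_perfectly_at_weak_penalty(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.5, size=(20, 2)), rng.normal(3, 0.5, size=(20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        fit = sv.fit_logreg(X, y, C=1e6)
        assert (fit.predict(X) == y).all()

    def test_strong_penalty_shrinks_to_prior(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 20 + [0] * 10)
        fit = sv.fit_logreg(X, y, C=1e-8)
        assert np.linalg.norm(fit.weights) < 1e-4
        np.testing.assert_allclose(fit.predict_proba(X), 2 / 3, atol=1e-3)

    def test_weight_norm_monotone_in_C(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        norms = [
            np.linalg.norm(sv.fit_logreg(X, y, C).weights)
            for C in 10.0 ** np.arange(-4, 3)
        ]
        assert all(b >= a - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            sv.fit_logreg(np.ones((4, 2)), np.ones(4), C=1.0)


class TestScores:
    def test_f1_weighted_frozen_example(self):
        assert sv.f1_weighted([1, 1, 1, 0, 0], [1, 1, 1, 0, 1]) == pytest.approx(
            82 / 105
        )

    def test_f1_bounds(self):
        assert sv.f1_weighted([0, 1], [0, 1]) == 1.0
        assert sv.f1_weighted([0, 1], [1, 0]) == 0.0

    def test_f1_empty_rejected(self):
        with pytest.raises(ValidationError):
            sv.f1_weighted([], [])

    def test_confusion_metrics_definitions(self):
        sens, spec = sv.confusion_metrics([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 1])
        assert sens == 1.0 and spec == pytest.approx(2 / 3)

    def test_confusion_metrics_undefined_is_none(self):
        sens, spec = sv.confusion_metrics([0, 0], [0, 1])
        assert sens is None and spec == 0.5

    def test_perfect_prediction(self):
        assert sv.confusion_metrics([1, 0], [1, 0]) == (1.0, 1.0)


class TestCrossValidation:
    def test_loo_has_one_fold_per_sampling_group(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        result = sv.cv_score(logged, np.arange(logged.n), n_top=10, C=1.0)
        n_groups = logged.meta.groupby(["subject_id", "status"]).ngroups
        assert len(result.folds) == n_groups

    def test_replicates_never_split_across_folds(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        groups = logged.groups()
        for train, test, _, _ in _folds(
            logged, np.arange(logged.n), "stratified_kfold", 3, seed=0
        ):
            assert not set(groups[train]) & set(groups[test])

    def test_strong_signal_scores_high(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        result = sv.cv_score(logged, np.arange(logged.n), n_top=20, C=0.1)
        assert result.score >= 0.9

    def test_shuffled_labels_score_near_chance(self, null_cohort):
        logged = sv.log_transform(null_cohort)
        scores = [
            sv.cv_score(
                logged, np.arange(logged.n), n_top=10, C=1.0,
                scheme="stratified_kfold", k=5, seed=s,
            ).score
            for s in range(3)
        ]
        assert 0.25 <= float(np.median(scores)) <= 0.75


class TestGridSearch:
    def test_single_cell(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        grid = sv.grid_search(logged, np.arange(logged.n), [0.5], [10])
        assert (grid.best_C, grid.best_N) == (0.5, 10)
        assert grid.surface[(0.5, 10)] == grid.best_score

    def test_n_beyond_library_rejected(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        with pytest.raises(ValidationError):
            sv.grid_search(logged, np.arange(logged.n), [1.0], [9999])


class TestHoldout:
    def test_group_overlap_raises_leakage_error(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        rows = np.arange(logged.n)
        with pytest.raises(LeakageError):
            sv.evaluate_holdout(logged, rows[:10], rows[5:20], C=1.0, n_top=5)

    def test_split_then_holdout_runs_clean(self, small_cohort):
        logged = sv.log_transform(small_cohort)
        train, test = sv.split_train_test(logged, np.arange(logged.n), 0.3, seed=0)
        assert not set(logged.groups()[train]) & set(logged.groups()[test])
        result = sv.evaluate_holdout(logged, train, test, C=0.1, n_top=20, seed=0)
        assert 0.0 <= result.f1 <= 1.0
        assert len(result.fit.weights) == 20
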