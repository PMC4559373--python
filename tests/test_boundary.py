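"""Boundary learning, discriminability bookkeeping, pairwise accuracy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from percat.boundary import (
    DiscriminabilityRecord,
    SplitResult,
    TaskDefinition,
    _inner_cv_choose_C,
    _standardize,
    _fit_logreg,
    discriminability,
    pairwise_accuracy,
    prediction_log,
    task_accuracy,
    train_eval_task,
    train_eval_multiclass,
)

from conftest import axis_mean, gaussian_descriptors

TASK_AB = TaskDefinition("ab", frozenset(["a"]), frozenset(["b"]))


def _make_task_data(separation, n=30, seed=0, dim=16):
    means = {"a": axis_mean(dim, 0, separation / 2), "b": axis_mean(dim, 0, -separation / 2)}
    return gaussian_descriptors(means, n, seed=seed, dim=dim)


class TestTaskDefinition:
    def test_rejects_overlap_and_empty(self):
        with pytest.raises(ValueError):
            TaskDefinition("x", frozenset(["a"]), frozenset(["a", "b"]))
        with pytest.raises(ValueError):
            TaskDefinition("x", frozenset(), frozenset(["b"]))


class TestTrainEvalTask:
    def test_separable_classes_are_perfectly_classified(self):
        desc, cats = _make_task_data(separation=30.0, n=25, seed=1)
        splits = train_eval_task(desc, cats, TASK_AB, n_splits=10, seed=2)
        assert len(splits) == 10
        assert all(s.test_accuracy == 1.0 for s in splits)

    def test_identical_distributions_give_chance_accuracy(self):
        desc, cats = _make_task_data(separation=0.0, n=100, seed=3)
        splits = train_eval_task(
            desc, cats, TASK_AB, n_splits=100, seed=4, c_grid=[1.0]
        )
        assert task_accuracy(splits) == pytest.approx(0.5, abs=0.08)

    def test_fixed_seed_is_deterministic(self):
        desc, cats = _make_task_data(separation=2.0, n=20, seed=5)
        a = train_eval_task(desc, cats, TASK_AB, n_splits=5, seed=6)
        b = train_eval_task(desc, cats, TASK_AB, n_splits=5, seed=6)
        for sa, sb in zip(a, b):
            assert sa.test_ids == sb.test_ids
            assert sa.test_predictions == sb.test_predictions
            assert sa.regularization == sb.regularization
            assert np.array_equal(sa.weights, sb.weights)

    def test_unbalanced_classes_are_subsampled_per_split(self):
        desc, cats = gaussian_descriptors(
            {"a": axis_mean(8, 0, 3), "b": axis_mean(8, 0, -3)}, 20, seed=7, dim=8
        )
        extra, cats_extra = gaussian_descriptors(
            {"b": axis_mean(8, 0, -3)}, 30, seed=8, dim=8
        )
        desc.update({f"x{k}": v for k, v in extra.items()})
        cats.update({f"x{k}": v for k, v in cats_extra.items()})
        splits = train_eval_task(desc, cats, TASK_AB, n_splits=4, seed=9)
        for s in splits:
            labels = list(s.test_true.values())
            assert labels.count("target") == labels.count("distractor")

    def test_split_accuracy_consistent_with_predictions(self):
        desc, cats = _make_task_data(separation=1.0, n=25, seed=10)
        for s in train_eval_task(desc, cats, TASK_AB, n_splits=5, seed=11):
            manual = np.mean(
                [s.test_predictions[i] == s.test_true[i] for i in s.test_ids]
            )
            assert s.test_accuracy == pytest.approx(manual)

    def test_too_few_images_per_class_rejected(self):
        desc, cats = _make_task_data(separation=1.0, n=1, seed=12)
        with pytest.raises(ValueError):
            train_eval_task(desc, cats, TASK_AB, n_splits=2, seed=0)

    def test_chosen_regularization_is_inner_cv_argmax(self):
        """The selected C equals the argmax of an exhaustive re-evaluation of
        the inner-CV grid with the same folds (independent oracle)."""
        from sklearn.model_selection import StratifiedKFold

        desc, cats = _make_task_data(separation=1.2, n=25, seed=13)
        ids = sorted(desc)
        X = np.vstack([desc[i] for i in ids])
        y = np.array([1 if cats[i] == "a" else 0 for i in ids])
        grid = [1e-3, 1e-1, 1e1]

        rng = np.random.default_rng(99)
        chosen, scores = _inner_cv_choose_C(X, y, grid, 5, rng)

        rng2 = np.random.default_rng(99)  # replay the same fold seed
        skf = StratifiedKFold(5, shuffle=True, random_state=int(rng2.integers(2**31 - 1)))
        oracle = np.zeros(len(grid))
        for tr, te in skf.split(X, y):
            Xtr, Xte = _standardize(X[tr], X[te])
            for ci, C in enumerate(grid):
                clf = _fit_logreg(Xtr, y[tr], C)
                oracle[ci] += (clf.predict(Xte) == y[te]).mean()
        oracle /= 5
        assert np.allclose(scores, oracle)
        assert chosen == grid[int(np.argmax(oracle))]

    def test_accuracy_monotone_in_class_separation(self):
        """Mean correct rate is non-decreasing in the true class margin."""
        accs = []
        for sep in (0.0, 1.0, 2.0, 4.0):
            per_dataset = []
            for rep in range(4):  # dataset-level draws dominate the variance
                desc, cats = _make_task_data(separation=sep, n=40, seed=20 + rep, dim=16)
                splits = train_eval_task(
                    desc, cats, TASK_AB, n_splits=15, seed=50 + rep, c_grid=[1.0]
                )
                recs = discriminability(splits)
                per_dataset.append(np.mean([r.correct_rate for r in recs]))
            accs.append(np.mean(per_dataset))
        for lo, hi in zip(accs, accs[1:]):
            assert hi >= lo - 0.03  # Monte-Carlo tolerance

    def test_decision_value_magnitude_tracks_correct_rate(self):
        desc, cats = _make_task_data(separation=1.5, n=50, seed=22)
        splits = train_eval_task(desc, cats, TASK_AB, n_splits=30, seed=23, c_grid=[1.0])
        recs = discriminability(splits)
        rho, _ = stats.spearmanr(
            [abs(r.mean_decision_value) for r in recs], [r.correct_rate for r in recs]
        )
        assert rho > 0


def _toy_splits():
    """Hand-built splits for bookkeeping arithmetic."""
    def mk(split_id, ids, true, pred, dval, acc):
        return SplitResult(
            split_id=split_id, weights=np.zeros(2), intercept=0.0, regularization=1.0,
            test_ids=tuple(ids), test_true=dict(zip(ids, true)),
            test_predictions=dict(zip(ids, pred)), test_decision_values=dict(zip(ids, dval)),
            test_accuracy=acc,
        )
    s1 = mk(0, ["i1", "i2"], ["target", "distractor"], ["target", "target"], [1.0, 0.5], 0.5)
    s2 = mk(1, ["i1", "i3"], ["target", "distractor"], ["target", "distractor"], [2.0, -1.0], 1.0)
    return [s1, s2]


class TestDiscriminability:
    def test_all_correct_and_all_wrong_rates(self):
        recs = {r.image_id: r for r in discriminability(_toy_splits())}
        assert recs["i1"].correct_rate == 1.0 and recs["i1"].test_appearances == 2
        assert recs["i2"].correct_rate == 0.0
        assert recs["i3"].correct_rate == 1.0
        assert recs["i1"].mean_decision_value == pytest.approx(1.5)

    def test_matches_brute_force_tally_of_prediction_log(self):
        desc, cats = _make_task_data(separation=1.0, n=30, seed=30)
        splits = train_eval_task(desc, cats, TASK_AB, n_splits=20, seed=31, c_grid=[1.0])
        log = prediction_log(splits)
        recs = discriminability(splits)
        for r in recs:
            sub = log[log["image_id"] == r.image_id]
            assert r.test_appearances == len(sub)
            assert r.correct_rate == (sub["true_label"] == sub["predicted_label"]).mean()
            assert r.mean_decision_value == pytest.approx(sub["decision_value"].mean())

    def test_missing_coverage_raises_with_ids(self):
        with pytest.raises(ValueError, match="ghost"):
            discriminability(_toy_splits(), expected_ids=["i1", "ghost"])


class TestTaskAccuracy:
    def test_mean_of_split_accuracies(self):
        assert task_accuracy(_toy_splits()) == pytest.approx(0.75)

    def test_equals_pooled_tally_for_equal_split_sizes(self):
        splits = _toy_splits()
        log = prediction_log(splits)
        pooled = (log["true_label"] == log["predicted_label"]).mean()
        assert task_accuracy(splits) == pytest.approx(pooled)


class TestPairwiseAccuracy:
    def _log(self, i_to_j, j_to_i, n=10):
        rows = []
        for k in range(n):
            rows.append((0, f"i{k}", "i", "j" if k < i_to_j else "i"))
            rows.append((0, f"j{k}", "j", "i" if k < j_to_i else "j"))
        return pd.DataFrame(
            rows, columns=["split_id", "image_id", "true_category", "predicted_category"]
        )

    def test_no_confusions_is_one(self):
        assert pairwise_accuracy(self._log(0, 0), "i", "j").acc == 1.0

    def test_total_confusion_is_zero(self):
        assert pairwise_accuracy(self._log(10, 10), "i", "j").acc == 0.0

    def test_counting_formula(self):
        # 2/10 i->j plus 3/10 j->i over 20 test images: acc = 1 - 5/20
        assert pairwise_accuracy(self._log(2, 3), "i", "j").acc == pytest.approx(0.75)

    def test_symmetry(self):
        log = self._log(2, 3)
        assert pairwise_accuracy(log, "i", "j").acc == pairwise_accuracy(log, "j", "i").acc

    def test_errors(self):
        with pytest.raises(ValueError):
            pairwise_accuracy(self._log(0, 0), "i", "i")
        with pytest.raises(ValueError):
            pairwise_accuracy(self._log(0, 0), "i", "zzz")

    def test_multiclass_log_on_separable_categories(self):
        means = {c: axis_mean(12, k, 8.0) for k, c in enumerate(["a", "b", "c"])}
        desc, cats = gaussian_descriptors(means, 15, seed=40, dim=12)
        log = train_eval_multiclass(desc, cats, n_splits=4, seed=41, c_grid=[1.0])
        for i, j in (("a", "b"), ("a", "c"), ("b", "c")):
            assert pairwise_accuracy(log, i, j).acc == 1.0
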