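"""Categorization boundaries: cross-validated L2 logistic regression.

A categorization task (target vs. distractor category sets) defines a linear
decision boundary in gist space.  The boundary is re-learned over many random
balanced 80/20 train/test splits; the per-split regularization strength is
chosen by 5-fold cross-validation on the training portion only.  Per-image
discriminability is the rate of correct test classification over the splits
in which the image appeared in a test set — a cheap, well-behaved proxy for
the distance between the image and the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "TaskDefinition",
    "SplitResult",
    "DiscriminabilityRecord",
    "PairwiseAccuracy",
    "DEFAULT_C_GRID",
    "train_eval_task",
    "discriminability",
    "task_accuracy",
    "prediction_log",
    "train_eval_multiclass",
    "pairwise_accuracy",
]

TARGET = "target"
DISTRACTOR = "distractor"

#: logarithmic regularization grid (inverse strength C), 7 points over 1e-3..1e3
DEFAULT_C_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 7))


@dataclass(frozen=True)
class TaskDefinition:
    """A binary categorization task over basic-category sets."""

    name: str
    target_categories: frozenset[str]
    distractor_categories: frozenset[str]
    level: str = "basic"  # attribute | basic | superordinate

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_categories", frozenset(self.target_categories))
        object.__setattr__(
            self, "distractor_categories", frozenset(self.distractor_categories)
        )
        if not self.target_categories or not self.distractor_categories:
            raise ValueError("target and distractor category sets must be non-empty")
        if self.target_categories & self.distractor_categories:
            raise ValueError("target and distractor category sets must be disjoint")

    def label_of(self, category: str) -> str | None:
        if category in self.target_categories:
            return TARGET
        if category in self.distractor_categories:
            return DISTRACTOR
        return None


@dataclass
class SplitResult:
    """One random train/test split: fitted boundary and its test outcomes."""

    split_id: int
    weights: np.ndarray
    intercept: float
    regularization: float
    test_ids: tuple[str, ...]
    test_true: dict[str, str]
    test_predictions: dict[str, str]
    test_decision_values: dict[str, float]
    test_accuracy: float


@dataclass
class DiscriminabilityRecord:
    """Cross-validated correct-classification rate for one image and task.

    ``correct_rate`` = 1 - average test classification error, so 1.0 is
    easiest (furthest from the boundary on the correct side).
    """

    image_id: str
    task: str
    test_appearances: int
    correct_rate: float
    mean_decision_value: float


@dataclass(frozen=True)
class PairwiseAccuracy:
    category_i: str
    category_j: str
    acc: float


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _fit_logreg(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    # L2 penalty (liblinear primal default)
    clf = LogisticRegression(C=C, solver="liblinear", max_iter=1000)
    clf.fit(X, y)
    return clf


def _inner_cv_choose_C(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float],
    n_folds: int,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Mean 5-fold CV accuracy per grid point; argmax (first max) wins."""
    if len(c_grid) == 1:
        return c_grid[0], np.array([np.nan])
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    folds = list(skf.split(X, y))
    for _, (tr, _te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                "a class is absent from an inner training fold; "
                "use more images per class or fewer folds"
            )
    scores = np.zeros(len(c_grid))
    for tr, te in folds:
        Xtr, Xte = _standardize(X[tr], X[te])
        for ci, C in enumerate(c_grid):
            clf = _fit_logreg(Xtr, y[tr], C)
            scores[ci] += (clf.predict(Xte) == y[te]).mean()
    scores /= len(folds)
    return c_grid[int(np.argmax(scores))], scores


def _task_arrays(
    descriptors: Mapping[str, np.ndarray],
    categories: Mapping[str, str],
    task: TaskDefinition,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids, X, y = [], [], []
    for img_id, vec in descriptors.items():
        label = task.label_of(categories[img_id])
        if label is None:
            continue
        ids.append(img_id)
        X.append(np.asarray(getattr(vec, "values", vec), dtype=float))
        y.append(1 if label == TARGET else 0)
    if not ids:
        raise ValueError(f"no images belong to task {task.name!r}")
    return np.array(ids), np.vstack(X), np.array(y)


def train_eval_task(
    descriptors: Mapping[str, np.ndarray],
    categories: Mapping[str, str],
    task: TaskDefinition,
    n_splits: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    *,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    inner_folds: int = 5,
) -> list[SplitResult]:
    """Learn the task boundary over ``n_splits`` random balanced splits.

    Per split: the larger class is subsampled to the smaller class's size
    (balanced positives/negatives), the balanced pool is split
    ``train_fraction`` / rest stratified by class, features are standardized
    with train-set statistics, the regularization is chosen by
    ``inner_folds``-fold CV on the training portion, and the refit boundary
    is evaluated on the held-out test images.  Decision values are signed
    distances proxies (positive = target side); ties at exactly 0 go to the
    target class.

    Images may recur across splits (sampling is with replacement across, but
    never within, splits).
    """
    ids, X, y = _task_arrays(descriptors, categories, task)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < 2:
        raise ValueError("need at least 2 images per class")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")

    child_seeds = np.random.SeedSequence(seed).spawn(n_splits)
    results: list[SplitResult] = []
    for split_id, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        # balance classes by subsampling the larger one
        n_per = min(n_pos, n_neg)
        pos_idx = rng.permutation(np.flatnonzero(y == 1))[:n_per]
        neg_idx = rng.permutation(np.flatnonzero(y == 0))[:n_per]
        # stratified train/test split of the balanced pool
        n_train = int(round(train_fraction * n_per))
        if n_train < inner_folds or n_train >= n_per:
            raise ValueError(
                f"train_fraction {train_fraction} leaves too few images for "
                f"training ({n_train}) or testing ({n_per - n_train}) per class"
            )
        tr_idx = np.concatenate([pos_idx[:n_train], neg_idx[:n_train]])
        te_idx = np.concatenate([pos_idx[n_train:], neg_idx[n_train:]])

        C, _scores = _inner_cv_choose_C(X[tr_idx], y[tr_idx], c_grid, inner_folds, rng)
        Xtr, Xte = _standardize(X[tr_idx], X[te_idx])
        clf = _fit_logreg(Xtr, y[tr_idx], C)
        dvals = Xte @ clf.coef_.ravel() + float(clf.intercept_[0])
        pred = np.where(dvals >= 0, 1, 0)  # ties to target
        acc = float((pred == y[te_idx]).mean())

        te_ids = ids[te_idx]
        results.append(
            SplitResult(
                split_id=split_id,
                weights=clf.coef_.ravel().copy(),
                intercept=float(clf.intercept_[0]),
                regularization=float(C),
                test_ids=tuple(te_ids),
                test_true={
                    i: (TARGET if t else DISTRACTOR) for i, t in zip(te_ids, y[te_idx])
                },
                test_predictions={
                    i: (TARGET if p else DISTRACTOR) for i, p in zip(te_ids, pred)
                },
                test_decision_values={i: float(d) for i, d in zip(te_ids, dvals)},
                test_accuracy=acc,
            )
        )
    return results


def discriminability(
    splits: Iterable[SplitResult],
    task: str = "",
    expected_ids: Iterable[str] | None = None,
) -> list[DiscriminabilityRecord]:
    """Per-image correct-classification rate and mean decision value.

    If ``expected_ids`` is given, raises (listing the offending ids) when any
    of them never appeared in a test set — the caller should raise n_splits.
    """
    splits = list(splits)
    if not splits:
        raise ValueError("no splits given")
    if expected_ids is not None:
        require_full_coverage(splits, expected_ids)
    appear: dict[str, int] = {}
    correct: dict[str, int] = {}
    dsum: dict[str, float] = {}
    for s in splits:
        for img_id in s.test_ids:
            appear[img_id] = appear.get(img_id, 0) + 1
            ok = s.test_predictions[img_id] == s.test_true[img_id]
            correct[img_id] = correct.get(img_id, 0) + int(ok)
            dsum[img_id] = dsum.get(img_id, 0.0) + s.test_decision_values[img_id]
    return [
        DiscriminabilityRecord(
            image_id=i,
            task=task,
            test_appearances=appear[i],
            correct_rate=correct[i] / appear[i],
            mean_decision_value=dsum[i] / appear[i],
        )
        for i in sorted(appear)
    ]


def require_full_coverage(
    splits: Iterable[SplitResult], expected_ids: Iterable[str]
) -> None:
    """Raise listing ids that never appeared in any test set."""
    tested = set()
    for s in splits:
        tested.update(s.test_ids)
    missing = sorted(set(expected_ids) - tested)
    if missing:
        raise ValueError(
            f"{len(missing)} image(s) never appeared in a test set "
            f"(raise n_splits): {missing[:10]}"
        )


def task_accuracy(splits: Sequence[SplitResult]) -> float:
    """Model accuracy for the task: mean per-split test accuracy."""
    if not splits:
        raise ValueError("no splits given")
    return float(np.mean([s.test_accuracy for s in splits]))


def prediction_log(splits: Iterable[SplitResult]) -> pd.DataFrame:
    """Long-format test prediction log (one row per test appearance)."""
    rows = [
        (
            s.split_id,
            img_id,
            s.test_true[img_id],
            s.test_predictions[img_id],
            s.test_decision_values[img_id],
        )
        for s in splits
        for img_id in s.test_ids
    ]
    return pd.DataFrame(
        rows,
        columns=["split_id", "image_id", "true_label", "predicted_label", "decision_value"],
    )


def train_eval_multiclass(
    descriptors: Mapping[str, np.ndarray],
    categories: Mapping[str, str],
    n_splits: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    *,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    inner_folds: int = 5,
) -> pd.DataFrame:
    """One-vs-all multi-class boundaries over random splits.

    Returns a log DataFrame (split_id, image_id, true_category,
    predicted_category) suitable for :func:`pairwise_accuracy`.
    """
    ids = np.array(list(descriptors.keys()))
    X = np.vstack(
        [np.asarray(getattr(descriptors[i], "values", descriptors[i]), float) for i in ids]
    )
    y = np.array([categories[i] for i in ids])
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError("need >= 2 categories")

    child_seeds = np.random.SeedSequence(seed).spawn(n_splits)
    rows = []
    for split_id, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        tr_parts, te_parts = [], []
        for c in cats:
            idx = rng.permutation(np.flatnonzero(y == c))
            n_train = int(round(train_fraction * len(idx)))
            if n_train < 2 or n_train >= len(idx):
                raise ValueError(f"category {c!r} too small for the requested split")
            tr_parts.append(idx[:n_train])
            te_parts.append(idx[n_train:])
        tr_idx = np.concatenate(tr_parts)
        te_idx = np.concatenate(te_parts)
        C, _ = _inner_cv_choose_C(X[tr_idx], y[tr_idx] == cats[0], c_grid, inner_folds, rng)
        Xtr, Xte = _standardize(X[tr_idx], X[te_idx])
        # one-vs-all: one boundary per category, argmax decision value
        scores = np.empty((len(te_idx), len(cats)))
        for k, c in enumerate(cats):
            clf = _fit_logreg(Xtr, (y[tr_idx] == c).astype(int), C)
            scores[:, k] = Xte @ clf.coef_.ravel() + float(clf.intercept_[0])
        pred = cats[np.argmax(scores, axis=1)]
        for i, p in zip(te_idx, pred):
            rows.append((split_id, ids[i], y[i], p))
    return pd.DataFrame(
        rows, columns=["split_id", "image_id", "true_category", "predicted_category"]
    )


def pairwise_accuracy(log: pd.DataFrame, i: str, j: str) -> PairwiseAccuracy:
    """acc(i, j) = 1 - fraction of i's test images labeled j and vice versa."""
    if i == j:
        raise ValueError("categories must differ")
    sub_i = log[log["true_category"] == i]
    sub_j = log[log["true_category"] == j]
    n = len(sub_i) + len(sub_j)
    if len(sub_i) == 0 or len(sub_j) == 0:
        raise ValueError(f"category with zero test images among ({i!r}, {j!r})")
    confusions = (sub_i["predicted_category"] == j).sum() + (
        sub_j["predicted_category"] == i
    ).sum()
    return PairwiseAccuracy(category_i=i, category_j=j, acc=1.0 - confusions / n)
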