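"""Class rebalancing, regularized logistic regression, CV scoring, grid search.

The classifier is an L2-penalized logistic regression (the model retained by
the study's automated pipeline search); hyperparameters are the inverse
regularization strength C and the number N of top-ranked descriptors.  All
data splits are group-aware: the technical replicates of one (subject,
status) sampling always stay on the same side of a split, and SMOTE
rebalancing is applied to learning rows only — synthetic rows never enter a
validation or test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.neighbors import NearestNeighbors

from .core import Dataset, StateError, ValidationError
from .preprocess import apply_scaler, fit_scaler, mannwhitney_rank, select_top


class LeakageError(RuntimeError):
    """Raised when train and test share a (subject, status) sampling group."""


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SMOTE: balance classes by convex interpolation in the minority class.

    Each synthetic point is x + u (x_nn - x) with u ~ Uniform(0, 1), x a
    random minority row and x_nn one of its k nearest minority neighbors
    (Euclidean).  Returns (X_out, y_out, synthetic_mask): original rows come
    first, unchanged, and the mask tags the appended synthetic rows so split
    hygiene can be audited.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if rng is None:
        rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"SMOTE needs 2 classes, got {classes.size}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValidationError("minority class needs >= 2 samples for SMOTE")
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X, y, np.zeros(len(y), dtype=bool)
    if k > n_min - 1:
        warnings.warn(
            f"SMOTE k={k} reduced to {n_min - 1} (minority size {n_min})",
            stacklevel=2,
        )
        k = n_min - 1
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    seeds = rng.integers(0, n_min, size=n_new)
    picks = neighbors[seeds, rng.integers(0, k, size=n_new)]
    u = rng.uniform(size=(n_new, 1))
    synth = X_min[seeds] + u * (X_min[picks] - X_min[seeds])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    mask = np.zeros(len(y_out), dtype=bool)
    mask[len(y):] = True
    return X_out, y_out, mask


@dataclass
class FitResult:
    """A fitted L2-logistic classifier on a descriptor subset."""

    weights: np.ndarray
    intercept: float
    C: float
    descriptor_ids: tuple[str, ...]
    train_groups: tuple[str, ...] = ()

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 = positive (pre-surgery) class."""
        return (self.decision_value(X) > 0).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_value(X)))


def fit_logreg(X: np.ndarray, y: np.ndarray, C: float, **meta) -> FitResult:
    """L2-penalized logistic regression: loss + (1/2C)·||w||² (lbfgs, tol 1e-8)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValidationError("fit_logreg needs both classes present")
    if C <= 0:
        raise ValidationError("C must be positive")
    clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-8, max_iter=10_000)
    clf.fit(X, y)
    return FitResult(
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        C=float(C),
        descriptor_ids=tuple(meta.get("descriptor_ids", ())),
        train_groups=tuple(meta.get("train_groups", ())),
    )


def f1_weighted(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 (zero-denominator F1 = 0)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValidationError("empty input to f1_weighted")
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


def confusion_metrics(
    y_true, y_pred, positive=1
) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) w.r.t. the positive label.

    Undefined ratios (empty denominator) are returned as None, never as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    neg = ~pos
    tp = int(np.sum(pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    tn = int(np.sum(neg & (y_pred != positive)))
    fp = int(np.sum(neg & (y_pred == positive)))
    sensitivity = tp / (tp + fn) if (tp + fn) else None
    specificity = tn / (tn + fp) if (tn + fp) else None
    return sensitivity, specificity


# ---------------------------------------------------------------------------
# group-aware splitting


def _group_table(dataset: Dataset, rows: np.ndarray):
    """Unique (subject|status) groups among rows, with labels and row lists."""
    rows = np.asarray(rows)
    keys = dataset.groups()[rows]
    labels = dataset.labels()[rows]
    group_rows: dict[str, list[int]] = {}
    group_label: dict[str, int] = {}
    for r, key, lab in zip(rows, keys, labels):
        group_rows.setdefault(key, []).append(int(r))
        group_label[key] = int(lab)
    names = sorted(group_rows)
    return names, group_rows, group_label


def split_train_test(
    dataset: Dataset, rows, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Group-aware, status-stratified train/test split over the given rows."""
    names, group_rows, group_label = _group_table(dataset, np.asarray(rows))
    rng = np.random.default_rng(seed)
    train_rows: list[int] = []
    test_rows: list[int] = []
    for lab in (0, 1):
        members = [g for g in names if group_label[g] == lab]
        rng.shuffle(members)
        n_test = max(1, int(round(test_fraction * len(members))))
        for g in members[:n_test]:
            test_rows.extend(group_rows[g])
        for g in members[n_test:]:
            train_rows.extend(group_rows[g])
    return np.sort(train_rows), np.sort(test_rows)


def _folds(dataset: Dataset, rows, scheme: str, k: int, seed: int):
    """Yield (train_rows, test_rows) pairs; folds split by sampling group."""
    names, group_rows, group_label = _group_table(dataset, np.asarray(rows))
    if scheme == "leave_one_out":
        assignments = {g: i for i, g in enumerate(names)}
        n_folds = len(names)
    elif scheme == "stratified_kfold":
        rng = np.random.default_rng(seed)
        assignments = {}
        for lab in (0, 1):
            members = [g for g in names if group_label[g] == lab]
            rng.shuffle(members)
            for i, g in enumerate(members):
                assignments[g] = i % k
        n_folds = k
    else:
        raise ValidationError(f"unknown cv scheme {scheme!r}")
    for fold in range(n_folds):
        test_groups = [g for g in names if assignments[g] == fold]
        train_groups = [g for g in names if assignments[g] != fold]
        if not test_groups:
            continue
        tr = np.sort([r for g in train_groups for r in group_rows[g]])
        te = np.sort([r for g in test_groups for r in group_rows[g]])
        yield tr, te, tuple(train_groups), tuple(test_groups)


def _prepare_fold(
    dataset: Dataset, train_rows: np.ndarray, test_rows: np.ndarray, n_top: int
):
    """Rank + select + scale using training rows only; return fold matrices."""
    ranked = mannwhitney_rank(dataset, train_rows)
    subset = select_top(ranked, min(n_top, dataset.library.size))
    idx = dataset.library.indices(subset)
    scaler = fit_scaler(dataset, train_rows)
    scaled = apply_scaler(dataset, scaler)
    X_train = scaled.areas[np.asarray(train_rows)][:, idx]
    X_test = scaled.areas[np.asarray(test_rows)][:, idx] if len(test_rows) else None
    return subset, X_train, X_test, ranked


@dataclass
class FoldRecord:
    train_groups: tuple[str, ...]
    test_groups: tuple[str, ...]
    test_rows: np.ndarray
    n_synthetic_train: int
    skipped: bool = False


@dataclass
class CVResult:
    score: float
    folds: list[FoldRecord] = field(default_factory=list)


def cv_score(
    dataset: Dataset,
    rows,
    n_top: int,
    C: float,
    scheme: str = "leave_one_out",
    k: int = 5,
    seed: int = 0,
    smote_k: int = 5,
) -> CVResult:
    """Group-aware cross-validated F1-weighted score at (C, N).

    Per fold, descriptor ranking, scaler fitting and SMOTE rebalancing all
    use training rows only; predictions over held-out rows are pooled and
    scored once.
    """
    if dataset.transform_state != "logged":
        raise StateError("cv_score expects a logged dataset")
    rows = np.asarray(rows)
    y = dataset.labels()
    pooled_true: list[int] = []
    pooled_pred: list[int] = []
    records: list[FoldRecord] = []
    rng = np.random.default_rng(seed)
    for train_rows, test_rows, train_groups, test_groups in _folds(
        dataset, rows, scheme, k, seed
    ):
        if np.unique(y[train_rows]).size < 2:
            warnings.warn(
                f"fold {test_groups} skipped: single-class training set",
                stacklevel=2,
            )
            records.append(FoldRecord(train_groups, test_groups, test_rows, 0, True))
            continue
        _, X_train, X_test, _ = _prepare_fold(dataset, train_rows, test_rows, n_top)
        X_bal, y_bal, synth = smote_oversample(
            X_train, y[train_rows], k=smote_k, rng=rng
        )
        fit = fit_logreg(X_bal, y_bal, C, train_groups=train_groups)
        pred = fit.predict(X_test)
        pooled_true.extend(y[test_rows])
        pooled_pred.extend(pred)
        records.append(
            FoldRecord(train_groups, test_groups, test_rows, int(synth.sum()))
        )
    if not pooled_true:
        raise ValidationError("no fold produced predictions")
    return CVResult(f1_weighted(pooled_true, pooled_pred), records)


@dataclass
class GridResult:
    """CV-score surface over (C, N) with lowest-complexity tie-breaking."""

    surface: dict[tuple[float, int], float]
    best_C: float
    best_N: int
    best_score: float
    tied: list[tuple[float, int]] = field(default_factory=list)


def grid_search(
    dataset: Dataset,
    rows,
    c_grid,
    n_grid,
    scheme: str = "leave_one_out",
    k: int = 5,
    seed: int = 0,
    smote_k: int = 5,
) -> GridResult:
    """Evaluate cv_score on every (C, N); pick the max, ties to lowest
    complexity (smallest N, then smallest C).  Invariant to grid order."""
    c_grid = list(c_grid)
    n_grid = list(n_grid)
    if not c_grid or not n_grid:
        raise ValidationError("grids must be non-empty")
    if any(n > dataset.library.size for n in n_grid):
        raise ValidationError("n_grid value exceeds library size")
    surface: dict[tuple[float, int], float] = {}
    for C in c_grid:
        for N in n_grid:
            surface[(float(C), int(N))] = cv_score(
                dataset, rows, N, C, scheme=scheme, k=k, seed=seed, smote_k=smote_k
            ).score
    best_score = max(surface.values())
    tied = sorted(
        [cn for cn, s in surface.items() if s == best_score],
        key=lambda cn: (cn[1], cn[0]),
    )
    best_C, best_N = tied[0]
    return GridResult(surface, best_C, best_N, best_score, tied)


@dataclass
class HoldoutResult:
    fit: FitResult
    f1: float
    sensitivity: float | None
    specificity: float | None
    y_true: np.ndarray
    y_pred: np.ndarray
    subset: list[str]


def evaluate_holdout(
    dataset: Dataset,
    train_rows,
    test_rows,
    C: float,
    n_top: int,
    seed: int = 0,
    smote_k: int = 5,
) -> HoldoutResult:
    """Final fit on SMOTE-rebalanced training rows; metrics on untouched test.

    Raises :class:`LeakageError` if train and test share a sampling group.
    """
    train_rows = np.asarray(train_rows)
    test_rows = np.asarray(test_rows)
    groups = dataset.groups()
    overlap = set(groups[train_rows]) & set(groups[test_rows])
    if overlap:
        raise LeakageError(f"train/test share sampling groups: {sorted(overlap)}")
    if dataset.transform_state != "logged":
        raise StateError("evaluate_holdout expects a logged dataset")
    y = dataset.labels()
    subset, X_train, X_test, _ = _prepare_fold(dataset, train_rows, test_rows, n_top)
    X_bal, y_bal, _ = smote_oversample(
        X_train, y[train_rows], k=smote_k, seed=seed
    )
    fit = fit_logreg(
        X_bal,
        y_bal,
        C,
        descriptor_ids=subset,
        train_groups=sorted(set(groups[train_rows])),
    )
    y_pred = fit.predict(X_test)
    y_true = y[test_rows]
    sens, spec = confusion_metrics(y_true, y_pred, positive=1)
    return HoldoutResult(
        fit, f1_weighted(y_true, y_pred), sens, spec, y_true, y_pred, subset
    )
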