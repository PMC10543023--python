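"""Brain-state classification on feature frames.

Blocked (no-shuffle) cross-validation on consecutive segments, a
ridge-regularized logistic-regression baseline with balanced class
weights (plus SVM and gradient-boosted trees), balanced accuracy, F1, and
consecutive-sample movement-detection metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.metrics
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "blocked_cv_folds",
    "train_classifier",
    "balanced_accuracy",
    "f1_score",
    "detection_rate",
    "false_alarms_per_minute",
    "evaluate",
    "EvalReport",
]


def blocked_cv_folds(n_rows: int, k: int = 3) -> list[np.ndarray]:
    """Split ``n_rows`` consecutive rows into ``k`` contiguous, ordered,
    near-equal test segments (earlier segments take the remainder). No
    shuffling — temporal order is the leakage defence."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n_rows < k:
        raise ValueError(f"{n_rows} rows cannot form {k} folds")
    return list(np.array_split(np.arange(n_rows), k))


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    model: str = "ridge_logistic",
    class_balanced: bool = True,
    seed: int = 0,
):
    """Fit one of the supported classifiers; deterministic given ``seed``.

    ``ridge_logistic`` is an L2-penalized logistic regression (C = 1.0);
    ``svm`` an RBF support vector machine; ``boosted_trees`` gradient
    boosting via XGBoost. With ``class_balanced`` the class weights are
    inversely proportional to class frequency.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training fold contains a single class")
    weight = "balanced" if class_balanced else None
    if model == "ridge_logistic":
        clf = LogisticRegression(
            C=1.0, class_weight=weight, max_iter=2000, random_state=seed,
        )
    elif model == "svm":
        clf = SVC(class_weight=weight, random_state=seed)
    elif model == "boosted_trees":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            n_estimators=60,
            max_depth=3,
            learning_rate=0.3,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        if class_balanced:
            counts = {c: (y == c).sum() for c in np.unique(y)}
            sample_weight = np.array([len(y) / (len(counts) * counts[c]) for c in y])
            clf.fit(np.asarray(X), y, sample_weight=sample_weight)
            return clf
    else:
        raise ValueError(f"unknown model {model!r}")
    clf.fit(np.asarray(X), y)
    return clf


def balanced_accuracy(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Mean of per-class recalls; chance = 1/n_classes regardless of class
    imbalance."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must align")
    return float(sklearn.metrics.balanced_accuracy_score(labels, predictions))


def f1_score(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Binary F1 = 2TP / (2TP + FP + FN); 0 when nothing positive exists."""
    return float(
        sklearn.metrics.f1_score(
            np.asarray(labels), np.asarray(predictions), zero_division=0
        )
    )


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    vals = np.asarray(values, dtype=bool).astype(int)
    d = np.diff(np.concatenate([[0], vals, [0]]))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detection_rate(
    labels: np.ndarray,
    predictions: np.ndarray,
    min_consecutive: int = 3,
) -> float:
    """Fraction of movement epochs detected.

    An epoch is a contiguous run of positive labels; it counts as detected
    iff it contains at least ``min_consecutive`` consecutive
    correctly-positive predictions (3 rows = 300 ms at the 100-ms feature
    interval). Raises if no positive epochs exist.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    labels = np.asarray(labels).astype(bool)
    predictions = np.asarray(predictions).astype(bool)
    epochs = _runs(labels)
    if not epochs:
        raise ValueError("no positive epochs in labels")
    detected = 0
    for start, stop in epochs:
        correct = labels[start:stop] & predictions[start:stop]
        if any(stop_ - start_ >= min_consecutive for start_, stop_ in _runs(correct)):
            detected += 1
    return detected / len(epochs)


def false_alarms_per_minute(
    labels: np.ndarray,
    predictions: np.ndarray,
    min_consecutive: int = 3,
    row_interval_s: float = 0.1,
) -> float:
    """Supplementary: rate of >= ``min_consecutive``-row positive-prediction
    runs lying entirely outside labeled epochs, per minute of recording."""
    labels = np.asarray(labels).astype(bool)
    predictions = np.asarray(predictions).astype(bool)
    alarms = sum(
        1
        for start, stop in _runs(predictions & ~labels)
        if stop - start >= min_consecutive and not labels[start:stop].any()
    )
    minutes = len(labels) * row_interval_s / 60.0
    return alarms / minutes if minutes > 0 else 0.0


@dataclass
class EvalReport:
    """Per-fold and pooled decoding metrics from blocked cross-validation."""

    model: str
    per_fold: list[dict]
    pooled: dict
    fold_bounds: list[tuple[int, int]]
    n_rows_dropped: int
    predictions: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | None = None) -> str:
        doc = {
            "model": self.model,
            "per_fold": self.per_fold,
            "pooled": self.pooled,
            "fold_bounds": [list(b) for b in self.fold_bounds],
            "n_rows_dropped": self.n_rows_dropped,
        }
        text = json.dumps(doc, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    model: str = "ridge_logistic",
    k: int = 3,
    min_consecutive: int = 3,
    class_balanced: bool = True,
    seed: int = 0,
) -> EvalReport:
    """Blocked-CV train/test loop with sample and detection metrics.

    NaN feature rows (artifact-masked) are dropped before folding, with
    the count reported. Per-fold metrics come from each held-out segment;
    pooled metrics from the test predictions concatenated in time order.
    Detection metrics are only computed where the fold has positive labels.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    keep = ~np.isnan(X).any(axis=1)
    n_dropped = int((~keep).sum())
    X, y = X[keep], y[keep]
    folds = blocked_cv_folds(len(y), k)
    pooled_pred = np.empty(len(y), dtype=y.dtype)
    per_fold: list[dict] = []
    bounds: list[tuple[int, int]] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        try:
            clf = train_classifier(
                X[train_idx], y[train_idx], model=model,
                class_balanced=class_balanced, seed=seed,
            )
        except ValueError as err:
            raise ValueError(f"fold {i}: {err}") from err
        pred = clf.predict(X[test_idx])
        pooled_pred[test_idx] = pred
        bounds.append((int(test_idx[0]), int(test_idx[-1]) + 1))
        fold_metrics = {
            "fold": i,
            "balanced_accuracy": balanced_accuracy(y[test_idx], pred),
            "f1": f1_score(y[test_idx], pred),
        }
        if np.asarray(y[test_idx]).astype(bool).any():
            fold_metrics["detection_rate"] = detection_rate(
                y[test_idx], pred, min_consecutive
            )
        per_fold.append(fold_metrics)
    pooled = {
        "balanced_accuracy": balanced_accuracy(y, pooled_pred),
        "f1": f1_score(y, pooled_pred),
    }
    if np.asarray(y).astype(bool).any():
        pooled["detection_rate"] = detection_rate(y, pooled_pred, min_consecutive)
    return EvalReport(
        model=model,
        per_fold=per_fold,
        pooled=pooled,
        fold_bounds=bounds,
        n_rows_dropped=n_dropped,
        predictions=pooled_pred,
        labels=y,
    )
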