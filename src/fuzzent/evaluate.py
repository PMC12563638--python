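"""Classifier benchmark, cross-validation protocols and channel selection.

Six standard classifiers are benchmarked on the fused entropy features,
identified by the short codes used throughout the reports:

    C1  linear-kernel SVM          C4  kNN, k = 5
    C2  RBF-kernel SVM             C5  Gaussian naive Bayes
    C3  kNN, k = 3                 C6  linear discriminant analysis

Three cross-validation schemes are provided.  Within a subject:
leave-one-out over the trials (LOOCV — deterministic) and stratified
10-fold (seeded).  Across subjects: leave-one-subject-out (LOSOCV),
where every trial of one subject is held out and the remaining
subjects' trials form the training set, measuring generalization to
unseen individuals.

Channel selection follows the representative-channel protocol: for each
subject the single channel whose features give the highest accuracy is
recorded, and occurrence counts over subjects identify montage-wide
representative electrodes.  Accuracy is the proportion of correct
predictions, reported as a percentage; the positive class is "lie".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from fuzzent.features import FeatureMatrix, standardize_train_apply
from fuzzent.io import MONTAGE

__all__ = [
    "CLASSIFIER_IDS",
    "ConfusionCounts",
    "ChannelReport",
    "make_classifier",
    "train_predict",
    "accuracy",
    "confusion_from_predictions",
    "run_loocv",
    "run_kfold",
    "run_losocv",
    "best_channel_per_subject",
    "aggregate_report",
]

CLASSIFIER_IDS = ("C1", "C2", "C3", "C4", "C5", "C6")

_CLASSIFIER_NAMES = {
    "C1": "SVM-Linear",
    "C2": "SVM-RBF",
    "C3": "kNN-3",
    "C4": "kNN-5",
    "C5": "GaussianNB",
    "C6": "LDA",
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with "lie" as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ChannelReport:
    """Representative channel per subject plus montage-wide tallies.

    Ties at the per-subject argmax are resolved to the first channel in
    montage order (AF3, T7, PZ, T8, AF4); all tied channels are kept in
    ``ties`` for inspection.
    """

    best_channel: dict[str, str]
    ties: dict[str, tuple[str, ...]]
    occurrence_counts: dict[str, int]


def make_classifier(clf_id: str, **overrides):
    """Instantiate one of the six benchmark classifiers.

    Hyperparameters follow the most common defaults: SVM C = 1 (RBF
    width by the 'scale' rule), kNN with Euclidean metric and uniform
    votes, LDA with the pooled-covariance (svd) solver and priors
    estimated from the training labels.
    """
    if clf_id not in CLASSIFIER_IDS:
        raise ValueError(f"unknown classifier id {clf_id!r}; expected {CLASSIFIER_IDS}")
    factories = {
        "C1": lambda: SVC(kernel="linear", C=1.0, **overrides),
        "C2": lambda: SVC(kernel="rbf", C=1.0, gamma="scale", **overrides),
        "C3": lambda: KNeighborsClassifier(n_neighbors=3, **overrides),
        "C4": lambda: KNeighborsClassifier(n_neighbors=5, **overrides),
        "C5": lambda: GaussianNB(**overrides),
        "C6": lambda: LinearDiscriminantAnalysis(**overrides),
    }
    return factories[clf_id]()


def train_predict(
    clf_id: str,
    Z_train: np.ndarray,
    y_train: np.ndarray,
    Z_test: np.ndarray,
) -> np.ndarray:
    """Fit one classifier and predict labels for the test rows."""
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    clf = make_classifier(clf_id)
    clf.fit(Z_train, y_train)
    return clf.predict(np.atleast_2d(Z_test)).astype(int)


def accuracy(c: ConfusionCounts) -> float:
    """Percentage of correctly classified samples."""
    if c.total == 0:
        raise ValueError("cannot compute accuracy on zero samples")
    return 100.0 * (c.tp + c.tn) / c.total


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _eval_folds(X, y, clf_id, folds, standardize=True):
    """Run train/test over explicit folds, pooling all test predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    y_pred = np.empty_like(y)
    tested = np.zeros(y.shape[0], dtype=bool)
    records = []
    for train_idx, test_idx in folds:
        if standardize:
            Z_train, Z_test, _ = standardize_train_apply(X[train_idx], X[test_idx])
        else:
            Z_train, Z_test = X[train_idx], X[test_idx]
        preds = train_predict(clf_id, Z_train, y[train_idx], Z_test)
        y_pred[test_idx] = preds
        if tested[test_idx].any():
            raise RuntimeError("a sample was assigned to more than one test fold")
        tested[test_idx] = True
        records.append({"test_idx": np.array(test_idx), "pred": preds})
    if not tested.all():
        raise RuntimeError("some samples were never tested")
    counts = confusion_from_predictions(y, y_pred)
    return {
        "accuracy": accuracy(counts),
        "confusion": counts,
        "predictions": y_pred,
        "fold_records": records,
        "n_folds": len(records),
    }


def run_loocv(X: np.ndarray, y: np.ndarray, clf_id: str, standardize: bool = True) -> dict:
    """Leave-one-out CV: one fold per trial, each tested exactly once.

    Deterministic — no randomness is involved in the fold assignment.
    """
    n = np.asarray(X).shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples for LOOCV, got {n}")
    folds = [
        (np.delete(np.arange(n), i), np.array([i]))
        for i in range(n)
    ]
    return _eval_folds(X, y, clf_id, folds, standardize)


def run_kfold(
    X: np.ndarray,
    y: np.ndarray,
    clf_id: str,
    k: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> dict:
    """Stratified k-fold CV with a seeded shuffle; accuracy pooled over folds."""
    y = np.asarray(y, dtype=int)
    if y.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {y.shape[0]}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.asarray(X), y))
    return _eval_folds(X, y, clf_id, folds, standardize)


def run_losocv(
    features_by_subject: dict[str, FeatureMatrix],
    clf_id: str,
    standardize: bool = True,
) -> dict:
    """Leave-one-subject-out CV over per-subject feature matrices.

    Each fold holds out every trial of one subject and trains on all
    trials of the others; the report carries per-subject accuracies and
    their mean.
    """
    subjects = list(features_by_subject)
    if len(subjects) < 2:
        raise ValueError("LOSOCV needs at least 2 subjects")
    per_subject: dict[str, float] = {}
    fold_records = []
    for test_subj in subjects:
        train_X = np.vstack(
            [features_by_subject[s].X for s in subjects if s != test_subj]
        )
        train_y = np.concatenate(
            [features_by_subject[s].y for s in subjects if s != test_subj]
        )
        test = features_by_subject[test_subj]
        if standardize:
            Z_train, Z_test, _ = standardize_train_apply(train_X, test.X)
        else:
            Z_train, Z_test = train_X, test.X
        preds = train_predict(clf_id, Z_train, train_y, Z_test)
        counts = confusion_from_predictions(test.y, preds)
        per_subject[test_subj] = accuracy(counts)
        fold_records.append({"subject": test_subj, "pred": preds, "confusion": counts})
    accs = np.array(list(per_subject.values()))
    return {
        "per_subject": per_subject,
        "mean": float(accs.mean()),
        "sd": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        "n_folds": len(subjects),
        "fold_records": fold_records,
    }


def best_channel_per_subject(
    accuracies: pd.DataFrame, montage: tuple[str, ...] = MONTAGE
) -> ChannelReport:
    """Representative channel per subject from a subject x channel table.

    ``accuracies`` has one row per subject (index = subject id) and one
    column per channel.  The argmax channel is selected per subject;
    ties are broken by montage order and logged in full.
    """
    missing = [c for c in accuracies.columns if accuracies[c].isna().any()]
    if missing:
        raise ValueError(f"missing accuracy cells in channel column(s) {missing}")
    best: dict[str, str] = {}
    ties: dict[str, tuple[str, ...]] = {}
    order = [c for c in montage if c in accuracies.columns] + [
        c for c in accuracies.columns if c not in montage
    ]
    for subject, row in accuracies.iterrows():
        top = row.max()
        tied = tuple(c for c in order if row[c] == top)
        best[str(subject)] = tied[0]
        if len(tied) > 1:
            ties[str(subject)] = tied
    counts = Counter(best.values())
    return ChannelReport(
        best_channel=best,
        ties=ties,
        occurrence_counts={c: counts.get(c, 0) for c in order if counts.get(c, 0)},
    )


def aggregate_report(report: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Append Mean and SD rows (sample standard deviation) to a report table.

    Aggregates are computed at full precision from the per-subject
    values and rounded only for display.
    """
    if report.empty:
        raise ValueError("cannot aggregate an empty report")
    numeric = report.select_dtypes(include=[np.number])
    if numeric.empty:
        raise ValueError("report has no numeric columns to aggregate")
    mean = numeric.mean(axis=0)
    sd = numeric.std(axis=0, ddof=1)
    out = report.copy()
    out.loc["Mean"] = mean.round(decimals)
    out.loc["SD"] = sd.round(decimals)
    return out
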