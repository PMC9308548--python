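"""Linear-SVM validation of the ego-gene signature.

Samples are split 6:4 (stratified per group); a linear soft-margin
classifier is trained on ego-gene methylation with the regularization
strength chosen from a fixed grid by stratified 5-fold cross-validation
(ties go to the smallest value); the held-out set yields AUC, accuracy,
MCC, sensitivity and specificity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SplitPlan", "FittedSVM", "ClassificationReport", "split_samples",
           "train_linear_svm", "evaluate", "rank_auc", "C_GRID"]

logger = logging.getLogger("methego")

C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class SplitPlan:
    """Stratified train/test partition of the samples."""

    train: list[str]
    test: list[str]
    group_counts: dict[str, tuple[int, int]]  # group -> (n_train, n_test)
    seed: int

    def validate(self) -> None:
        assert not set(self.train) & set(self.test)


def split_samples(samples: list[str], groups: pd.Series,
                  train_fraction: float = 0.6, seed: int = 0) -> SplitPlan:
    """Random stratified split: round(train_fraction · n_g) per group.

    Deterministic given the seed.  A group that would land entirely in one
    partition raises an error.
    """
    rng = np.random.default_rng(seed)
    groups = groups.loc[samples]
    train: list[str] = []
    test: list[str] = []
    counts: dict[str, tuple[int, int]] = {}
    for label in sorted(groups.unique()):
        members = sorted(groups.index[groups == label])
        n_train = int(round(train_fraction * len(members)))
        if n_train < 1 or len(members) - n_train < 1:
            raise ValueError(
                f"group {label!r} with {len(members)} sample(s) cannot appear in "
                "both partitions at this split fraction"
            )
        perm = rng.permutation(len(members))
        train += [members[i] for i in perm[:n_train]]
        test += [members[i] for i in perm[n_train:]]
        counts[label] = (n_train, len(members) - n_train)
    plan = SplitPlan(sorted(train), sorted(test), counts, seed)
    plan.validate()
    return plan


@dataclass
class FittedSVM:
    """A trained linear classifier with its CV selection record."""

    model: SVC
    scaler: StandardScaler | None
    C: float
    cv_accuracies: dict[float, float]  # C -> mean CV accuracy
    fold_accuracies: list[float]  # per-fold accuracies at the chosen C
    positive_label: str
    classes: tuple[str, str]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.model.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes[1], self.classes[0])


def train_linear_svm(X: np.ndarray, y: np.ndarray, positive_label: str,
                     cv_folds: int = 5, seed: int = 0,
                     standardize: bool = True,
                     c_grid: tuple[float, ...] = C_GRID) -> FittedSVM:
    """Train a linear soft-margin classifier with CV-selected C.

    ``positive_label`` names the class scored positively by the decision
    function.  Each class needs at least ``cv_folds`` training samples so
    every CV fold sees both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(set(y))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, got {labels}")
    if positive_label not in labels:
        raise ValueError(f"positive label {positive_label!r} not among {labels}")
    negative_label = next(l for l in labels if l != positive_label)
    classes = (negative_label, positive_label)
    y01 = (y == positive_label).astype(int)
    class_counts = np.bincount(y01, minlength=2)
    if class_counts.min() < cv_folds:
        raise ValueError(
            f"stratification error: smallest class has {class_counts.min()} training "
            f"sample(s) but {cv_folds}-fold CV requires at least {cv_folds}"
        )

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y01))
    cv_acc: dict[float, float] = {}
    fold_acc_by_c: dict[float, list[float]] = {}
    for C in c_grid:
        accs = []
        for tr, va in folds:
            scaler = StandardScaler().fit(X[tr]) if standardize else None
            Xtr = scaler.transform(X[tr]) if scaler else X[tr]
            Xva = scaler.transform(X[va]) if scaler else X[va]
            clf = SVC(kernel="linear", C=C).fit(Xtr, y01[tr])
            accs.append(float((clf.predict(Xva) == y01[va]).mean()))
        cv_acc[C] = float(np.mean(accs))
        fold_acc_by_c[C] = accs
    # ties go to the smallest C: iterate the ascending grid with strict >
    best_c = c_grid[0]
    for C in c_grid:
        if cv_acc[C] > cv_acc[best_c]:
            best_c = C

    scaler = StandardScaler().fit(X) if standardize else None
    Xs = scaler.transform(X) if scaler else X
    model = SVC(kernel="linear", C=best_c).fit(Xs, y01)
    logger.info("train_linear_svm: chose C=%g (CV accuracy %.3f)", best_c, cv_acc[best_c])
    return FittedSVM(model, scaler, best_c, cv_acc, fold_acc_by_c[best_c],
                     positive_label, classes)


def rank_auc(scores: np.ndarray, y_positive: np.ndarray) -> float:
    """Rank-based AUC: Mann–Whitney statistic / (n₊·n₋), ties counted ½."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_positive, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: test set contains a single class")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ClassificationReport:
    """Confusion counts plus the five performance metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None
    accuracy: float
    mcc: float
    sensitivity: float
    specificity: float
    C: float | None = None
    cv_fold_accuracies: list[float] = field(default_factory=list)
    auc_missing_reason: str | None = None

    def to_series(self) -> pd.Series:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "auc": self.auc if self.auc is not None else np.nan,
            "accuracy": self.accuracy, "mcc": self.mcc,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "C": self.C if self.C is not None else np.nan,
        }
        for i, acc in enumerate(self.cv_fold_accuracies, start=1):
            d[f"cv_fold_{i}_accuracy"] = acc
        return pd.Series(d)


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int
                           ) -> tuple[float, float, float, float]:
    """(accuracy, mcc, sensitivity, specificity) with 0-denominator → 0/NaN."""
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else float("nan")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return accuracy, mcc, sens, spec


def evaluate(fitted: FittedSVM, X_test: np.ndarray, y_test: np.ndarray
             ) -> tuple[ClassificationReport, np.ndarray]:
    """Score the held-out samples and assemble the report.

    Predictions threshold the signed decision score at 0.  AUC is the
    rank-based Mann–Whitney form; on a single-class test set it is
    reported as missing with a reason instead of a number.
    """
    X_test = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test)
    if len(y) == 0:
        raise ValueError("empty test set")
    scores = fitted.decision_function(X_test)
    y_pos = y == fitted.positive_label
    pred_pos = scores > 0
    tp = int((pred_pos & y_pos).sum())
    fp = int((pred_pos & ~y_pos).sum())
    tn = int((~pred_pos & ~y_pos).sum())
    fn = int((~pred_pos & y_pos).sum())
    accuracy, mcc, sens, spec = metrics_from_confusion(tp, fp, tn, fn)
    auc: float | None
    reason = None
    try:
        auc = rank_auc(scores, y_pos)
    except ValueError as exc:
        auc = None
        reason = str(exc)
        logger.warning("evaluate: %s", reason)
    report = ClassificationReport(tp, fp, tn, fn, auc, accuracy, mcc, sens, spec,
                                  C=fitted.C, cv_fold_accuracies=fitted.fold_accuracies,
                                  auc_missing_reason=reason)
    return report, scores
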