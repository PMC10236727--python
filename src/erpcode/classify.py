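"""Within-subject single-trial classification and evaluation.

Trials are instances and channels are feature columns.  Two classifiers are
evaluated with leave-one-out (LOO) cross-validation, the natural choice for
a 135-trial session: an RBF-kernel SVM whose (C, gamma) are tuned by inner
k-fold grid search on each training fold (no leakage into the held-out
trial), and k-nearest neighbors with k = 5 and Euclidean distance.  Reported
metrics: sensitivity, specificity, accuracy, precision (percent) and the
ROC/AUC, with the rare "target" event as the positive class.  Chance level
under the 40/95 imbalance is 95/135 ~ 70.4% accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_SVM_GRID",
    "ClassifierSpec",
    "ConfusionCounts",
    "MetricsReport",
    "tune_svm_rbf",
    "loo_evaluate",
    "nested_loo_svm",
    "confusion_counts",
    "classification_metrics",
    "roc_auc",
    "evaluate_subject",
]

#: (C, gamma) candidates for the inner grid search.
DEFAULT_SVM_GRID: list[tuple[float, float]] = [
    (c, g) for c in (0.1, 1.0, 10.0, 100.0) for g in (1e-3, 1e-2, 1e-1, 1.0)
]

POSITIVE, NEGATIVE = "target", "standard"


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm_rbf"            # "svm_rbf" | "knn"
    C: float = 1.0
    gamma: float = 0.1
    k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("svm_rbf", "knn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd count for binary voting")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int
    positive_class: str = POSITIVE

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    sen: float | None
    spc: float | None
    acc: float | None
    prc: float | None
    auc: float | None = None
    roc_points: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"accuracy": self.acc, "sensitivity": self.sen,
                "specificity": self.spc, "precision": self.prc,
                "auc": self.auc}


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    bad = set(labels) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"labels outside the binary set: {sorted(bad)}")
    return labels


def _fit_predict(spec: ClassifierSpec, x_train, y_train, x_test):
    """Fit one model and return (predicted labels, positive-class scores)."""
    if spec.kind == "svm_rbf":
        model = SVC(C=spec.C, gamma=spec.gamma, kernel="rbf")
        model.fit(x_train, y_train)
        pred = model.predict(x_test)
        score = model.decision_function(x_test)
        if model.classes_[1] != POSITIVE:      # orient toward "target"
            score = -score
        return pred, score
    model = KNeighborsClassifier(n_neighbors=spec.k)
    model.fit(x_train, y_train)
    pred = model.predict(x_test)
    # decision score: fraction of the k neighbors voting for the positive class
    neigh = model.kneighbors(x_test, return_distance=False)
    votes = np.asarray(y_train, dtype=object)[neigh]
    score = (votes == POSITIVE).mean(axis=1)
    return pred, score


def tune_svm_rbf(features: np.ndarray, labels: np.ndarray,
                 grid: list[tuple[float, float]] | None = None,
                 folds: int = 5, seed: int = 0) -> tuple[float, float]:
    """Select (C, gamma) maximizing mean inner-CV accuracy.

    Deterministic: stratified folds are shuffled by ``seed`` and ties break
    toward smaller C, then smaller gamma.
    """
    grid = DEFAULT_SVM_GRID if grid is None else list(grid)
    if not grid:
        raise ValueError("empty grid")
    labels = _check_binary(labels)
    features = np.asarray(features, dtype=float)
    _, counts = np.unique(labels.astype(str), return_counts=True)
    n_splits = min(folds, counts.min())
    if n_splits < 2:
        return min(grid)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(features, labels.astype(str)))
    best = None
    for c, g in sorted(grid):
        correct = 0
        for train_idx, test_idx in splits:
            spec = ClassifierSpec("svm_rbf", C=c, gamma=g)
            pred, _ = _fit_predict(spec, features[train_idx],
                                   labels[train_idx], features[test_idx])
            correct += int((pred == labels[test_idx]).sum())
        if best is None or correct > best[0]:
            best = (correct, (c, g))
    return best[1]


def loo_evaluate(features: np.ndarray, labels: np.ndarray,
                 spec: ClassifierSpec) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out evaluation with a fixed classifier.

    N trials -> N folds; each trial is predicted once by a model that never
    saw it.  Returns (predictions, positive-class decision scores).
    """
    labels = _check_binary(labels)
    features = np.asarray(features, dtype=float)
    n = len(labels)
    for cls in (POSITIVE, NEGATIVE):
        if (labels == cls).sum() < 2:
            raise ValueError(f"need >= 2 trials of class {cls!r}")
    if np.allclose(features.std(axis=0), 0):
        warnings.warn("feature matrix has zero variance in every column")
    preds = np.empty(n, dtype=object)
    scores = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        pred, score = _fit_predict(spec, features[train], labels[train],
                                   features[i:i + 1])
        preds[i], scores[i] = pred[0], score[0]
    return preds, scores


def nested_loo_svm(features: np.ndarray, labels: np.ndarray,
                   grid: list[tuple[float, float]] | None = None,
                   inner_folds: int = 5, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """LOO evaluation of the RBF SVM with leakage-free nested tuning: (C,
    gamma) are re-selected on every training fold before predicting the
    held-out trial.  Returns (predictions, scores, per-fold selections)."""
    labels = _check_binary(labels)
    features = np.asarray(features, dtype=float)
    n = len(labels)
    preds = np.empty(n, dtype=object)
    scores = np.empty(n)
    chosen = []
    for i in range(n):
        train = np.arange(n) != i
        c, g = tune_svm_rbf(features[train], labels[train], grid,
                            folds=inner_folds, seed=seed)
        pred, score = _fit_predict(ClassifierSpec("svm_rbf", C=c, gamma=g),
                                   features[train], labels[train],
                                   features[i:i + 1])
        preds[i], scores[i] = pred[0], score[0]
        chosen.append((c, g))
    return preds, scores, chosen


def confusion_counts(predictions: np.ndarray, labels: np.ndarray,
                     positive_class: str = POSITIVE) -> ConfusionCounts:
    """Standard 2x2 tabulation of predictions against true labels."""
    predictions = np.asarray(predictions, dtype=object)
    labels = _check_binary(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    _check_binary(predictions)
    pos_true = labels == positive_class
    pos_pred = predictions == positive_class
    return ConfusionCounts(
        tp=int((pos_true & pos_pred).sum()),
        fn=int((pos_true & ~pos_pred).sum()),
        tn=int((~pos_true & ~pos_pred).sum()),
        fp=int((~pos_true & pos_pred).sum()),
        positive_class=positive_class)


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator")
        return None
    return 100.0 * num / den


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy and precision in percent:
    SEN = 100 TP/(TP+FN), SPC = 100 TN/(TN+FP),
    ACC = 100 (TP+TN)/total, PRC = 100 TP/(TP+FP)."""
    return MetricsReport(
        sen=_ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        spc=_ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        acc=_ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        prc=_ratio(counts.tp, counts.tp + counts.fp, "precision"))


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            positive_class: str = POSITIVE
            ) -> tuple[np.ndarray, float]:
    """ROC staircase (FPR, TPR) and its area.

    The area equals the Mann-Whitney probability that a random positive
    trial outscores a random negative one, counting ties as one half.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = (labels == positive_class).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate_subject(features: np.ndarray, labels: np.ndarray,
                     grid: list[tuple[float, float]] | None = None,
                     k: int = 5, inner_folds: int = 5, seed: int = 0,
                     nested: bool = True) -> dict[str, MetricsReport]:
    """LOO-evaluate both classifiers on one subject's feature matrix."""
    out: dict[str, MetricsReport] = {}
    if nested:
        svm_pred, svm_score, _ = nested_loo_svm(features, labels, grid,
                                                inner_folds, seed)
    else:
        c, g = tune_svm_rbf(features, labels, grid, folds=inner_folds,
                            seed=seed)
        svm_pred, svm_score = loo_evaluate(features, labels,
                                           ClassifierSpec("svm_rbf", C=c,
                                                          gamma=g))
    knn_pred, knn_score = loo_evaluate(features, labels,
                                       ClassifierSpec("knn", k=k))
    for name, (pred, score) in {"svm": (svm_pred, svm_score),
                                "knn": (knn_pred, knn_score)}.items():
        report = classification_metrics(confusion_counts(pred, labels))
        report.roc_points, report.auc = roc_auc(score, labels)
        out[name] = report
    return out
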