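"""Classification evaluation: confusion matrices, per-class sensitivity and
precision, accuracy, one-vs-rest ROC curves, and the standard baseline
classifiers (DT, KNN, LDA, NB, MLP, SVM) used for side-by-side comparison.

The baselines are a comparison harness, not the contribution: they run with
scikit-learn defaults and a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn import metrics as _skm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (zero support / single class)."""


@dataclass
class ConfusionMatrix:
    """counts[true_class][predicted_class] with ordered class names."""

    counts: np.ndarray
    class_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if not self.class_names:
            self.class_names = [str(i) for i in range(self.counts.shape[0])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self, c: int) -> int:
        return int(self.counts[c].sum())


def confusion(y_true, y_pred, num_classes: int,
              class_names: Optional[Sequence[str]] = None) -> ConfusionMatrix:
    """Count matrix counts[t][p] = #{i : y_true_i = t and y_pred_i = p}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    counts = _skm.confusion_matrix(y_true, y_pred,
                                   labels=np.arange(num_classes))
    return ConfusionMatrix(counts, class_names or [])


def sensitivity(cm: ConfusionMatrix, c: int) -> float:
    """Per-class recall: diagonal over the row sum."""
    row = cm.counts[c]
    if row.sum() == 0:
        raise UndefinedMetricError(f"class {c} has zero support")
    return float(cm.counts[c, c] / row.sum())


def precision(cm: ConfusionMatrix, c: int) -> float:
    """Positive predictive value: diagonal over the column sum."""
    col = cm.counts[:, c]
    if col.sum() == 0:
        raise UndefinedMetricError(f"class {c} never predicted")
    return float(cm.counts[c, c] / col.sum())


def accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total count."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def roc_points(scores, y_true):
    """Binary ROC curve by threshold sweep plus trapezoidal AUC.

    Returns (fpr, tpr, auc); the curve starts at (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise UndefinedMetricError("ROC needs both classes present")
    fpr, tpr, _ = _skm.roc_curve(y_true, scores, drop_intermediate=False)
    return fpr, tpr, float(_skm.auc(fpr, tpr))


def multiclass_roc(scores, y_true, num_classes: int) -> Dict[int, tuple]:
    """One-vs-rest ROC per class.

    ``scores`` may be a single column (e.g. the FWNNet pre-rounding output,
    used as-is for every class with the class index as the positive side of
    a distance score) or an (n, num_classes) score matrix.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    out = {}
    for c in range(num_classes):
        binary = (y_true == c).astype(int)
        if scores.ndim == 2:
            s = scores[:, c]
        else:
            # closeness of the continuous output to the class label
            s = -np.abs(scores - c)
        try:
            out[c] = roc_points(s, binary)
        except UndefinedMetricError:
            continue
    return out


BASELINE_NAMES = ("DT", "KNN", "LDA", "NB", "MLP", "SVM")


def _make_baseline(name: str, seed: int):
    """Library-default estimator behind a feature standardizer.

    The scaler keeps the scale-sensitive baselines (KNN, MLP, SVM) honest on
    intensity-scale features; the estimators themselves use defaults."""
    if name == "DT":
        est = DecisionTreeClassifier(random_state=seed)
    elif name == "KNN":
        est = KNeighborsClassifier()
    elif name == "LDA":
        est = LinearDiscriminantAnalysis()
    elif name == "NB":
        est = GaussianNB()
    elif name == "MLP":
        est = MLPClassifier(random_state=seed, max_iter=1000)
    elif name == "SVM":
        est = SVC(random_state=seed)
    else:
        raise ValueError(
            f"unknown baseline {name!r}; choose from {BASELINE_NAMES}")
    return make_pipeline(StandardScaler(), est)


@dataclass
class BaselineReport:
    name: str
    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: np.ndarray  # per class
    precision: np.ndarray    # per class (NaN where undefined)
    params: dict


def metrics_from_confusion(cm: ConfusionMatrix):
    C = cm.counts.shape[0]
    sens = np.full(C, np.nan)
    prec = np.full(C, np.nan)
    for c in range(C):
        if cm.counts[c].sum():
            sens[c] = sensitivity(cm, c)
        if cm.counts[:, c].sum():
            prec[c] = precision(cm, c)
    return accuracy(cm), sens, prec


def run_baselines(X_train, y_train, X_test, y_test,
                  baselines: Sequence[str] = BASELINE_NAMES,
                  seed: int = 0) -> Dict[str, BaselineReport]:
    """Fit each requested baseline and score it on the test set."""
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train, int)
    y_test = np.asarray(y_test, int)
    num_classes = int(max(y_train.max(), y_test.max())) + 1
    out = {}
    for name in baselines:
        clf = _make_baseline(name, seed)
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
        cm = confusion(y_test, pred, num_classes)
        acc, sens, prec = metrics_from_confusion(cm)
        out[name] = BaselineReport(name=name, confusion=cm, accuracy=acc,
                                   sensitivity=sens, precision=prec,
                                   params=clf.get_params())
    return out


def stratified_split(y, test_fraction: float = 0.3, seed: int = 0):
    """Seeded stratified train/test index split."""
    y = np.asarray(y, int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * idx.size))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(test_idx)))
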