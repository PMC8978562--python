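"""Classification metrics, confusion matrices, and repeated cross-validation.

Per-class precision, recall and F1 are computed one-vs-rest from a pooled
confusion matrix; accuracy is the trace of the confusion matrix over the
total.  Any metric whose denominator is zero is reported as 0, which keeps
macro averages defined on small test folds.  Run-to-run dispersion is the
population standard deviation of per-repeat accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .preprocess import DiscreteFeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "class_metrics",
    "run_std",
    "cross_validate",
    "make_classifier",
    "BUNDLED_CLASSIFIERS",
]


@dataclass
class ConfusionMatrix:
    """C×C counts; rows index the true class, columns the predicted class."""

    counts: np.ndarray
    classes: List

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if len(self.classes) != self.counts.shape[0]:
            raise ValueError("class labels must match matrix dimension")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def add(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if list(self.classes) != list(other.classes):
            raise ValueError("confusion matrices index different classes")
        return ConfusionMatrix(self.counts + other.counts, list(self.classes))


@dataclass
class MetricsReport:
    per_class: Dict[object, Dict[str, float]]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: Optional[ConfusionMatrix] = None
    run_accuracies: List[float] = field(default_factory=list)
    mean_accuracy: Optional[float] = None
    std: Optional[float] = None

    def to_dict(self) -> dict:
        out = {
            "per_class": {str(k): dict(v) for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
        }
        if self.confusion is not None:
            out["confusion"] = {
                "classes": [str(c) for c in self.confusion.classes],
                "counts": self.confusion.counts.tolist(),
            }
        if self.run_accuracies:
            out["runs"] = {
                "accuracies": list(self.run_accuracies),
                "mean": self.mean_accuracy,
                "std": self.std,
            }
        return out


def confusion_matrix(truth: Sequence, predicted: Sequence) -> ConfusionMatrix:
    """Count (true, predicted) pairs over the union of observed classes."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.ndim != 1 or p.ndim != 1 or t.size != p.size:
        raise ValueError("truth and predicted must be equal-length 1-D sequences")
    if t.size == 0:
        raise ValueError("empty inputs")
    classes = sorted(set(t.tolist()) | set(p.tolist()))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for ti, pi in zip(t.tolist(), p.tolist()):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts, classes)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class, global accuracy, macro means."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: Dict[object, Dict[str, float]] = {}
    for i, cls in enumerate(cm.classes):
        tp = float(cm.counts[i, i])
        fp = float(cm.counts[:, i].sum() - tp)
        fn = float(cm.counts[i, :].sum() - tp)
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * precision * recall, precision + recall)
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
    accuracy = float(np.trace(cm.counts)) / cm.total
    n = len(cm.classes)
    return MetricsReport(
        per_class=per_class,
        accuracy=accuracy,
        macro_precision=sum(v["precision"] for v in per_class.values()) / n,
        macro_recall=sum(v["recall"] for v in per_class.values()) / n,
        macro_f1=sum(v["f1"] for v in per_class.values()) / n,
        confusion=cm,
    )


def run_std(accuracies: Sequence[float]) -> float:
    """Population standard deviation of per-run accuracies."""
    a = np.asarray(accuracies, dtype=float)
    if a.size == 0:
        raise ValueError("at least one run accuracy is required")
    if np.all(a == a[0]):  # exact zero for identical runs
        return 0.0
    return float(np.sqrt(np.mean((a - a.mean()) ** 2)))


class _SafeCategoricalNB:
    """Categorical naive Bayes tolerant of category codes unseen in training.

    At predict time codes above the fitted per-feature maximum are clipped
    into range; such codes carry no training evidence either way, and the
    clip keeps small cross-validation folds from failing.
    """

    def __init__(self, alpha: float = 1.0):
        from sklearn.naive_bayes import CategoricalNB

        self._nb = CategoricalNB(alpha=alpha)
        self._max_codes: Optional[np.ndarray] = None

    def fit(self, X, y):
        X = np.asarray(X)
        self._max_codes = X.max(axis=0)
        self._nb.fit(X, y)
        return self

    def predict(self, X):
        X = np.minimum(np.asarray(X), self._max_codes)
        return self._nb.predict(X)


def make_classifier(name: str, seed: int = 0) -> Callable[[], object]:
    """Factory of fresh estimators for the bundled classifier names.

    ``knn1`` — one-nearest-neighbour; ``naive_bayes`` — categorical naive
    Bayes; ``tree`` — CART decision tree; ``majority`` — predicts the most
    frequent training class (a floor baseline).  Any other estimator with a
    fit/predict contract can be passed to the evaluation functions directly.
    """
    from sklearn.dummy import DummyClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.tree import DecisionTreeClassifier

    factories = {
        "knn1": lambda: KNeighborsClassifier(n_neighbors=1),
        "naive_bayes": lambda: _SafeCategoricalNB(),
        "tree": lambda: DecisionTreeClassifier(random_state=seed),
        "majority": lambda: DummyClassifier(strategy="most_frequent"),
    }
    if name not in factories:
        raise ValueError(f"unknown classifier {name!r}; expected {sorted(factories)}")
    return factories[name]


BUNDLED_CLASSIFIERS = ("knn1", "naive_bayes", "tree", "majority")


def cross_validate(
    m: DiscreteFeatureMatrix,
    feature_subset: Sequence[str],
    classifier_factory: Callable[[], object],
    k_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    stratified: bool = True,
    per_class_mode: str = "pooled",
) -> MetricsReport:
    """Repeated k-fold cross-validation of a classifier on a feature subset.

    Each repeat's accuracy (fraction correct over that repeat's pooled test
    predictions) is one ACC_i; the report carries their mean and population
    standard deviation.  Per-class metrics come from the confusion matrix
    pooled over all folds and repeats (``per_class_mode="pooled"``), or as
    the unweighted mean of fold-wise metrics (``"averaged"``).
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if k_folds < 2 or k_folds > m.n_samples:
        raise ValueError("k_folds must be in [2, n_samples]")
    if per_class_mode not in ("pooled", "averaged"):
        raise ValueError("per_class_mode must be 'pooled' or 'averaged'")
    cols = [m.feature_ids.index(fid) for fid in feature_subset]
    X = m.values[:, cols]
    y = m.label_codes
    classes = sorted(np.unique(y).tolist())

    pooled = ConfusionMatrix(
        np.zeros((len(classes), len(classes)), dtype=np.int64), classes
    )
    fold_reports: List[MetricsReport] = []
    run_accs: List[float] = []
    for rep in range(n_repeats):
        splitter_cls = StratifiedKFold if stratified else KFold
        splitter = splitter_cls(n_splits=k_folds, shuffle=True, random_state=seed + rep)
        correct = 0
        for train, test in splitter.split(X, y):
            if np.unique(y[train]).size < len(classes):
                warnings.warn(
                    "a class is absent from a training fold; its test samples "
                    "cannot be predicted correctly",
                    stacklevel=2,
                )
            clf = classifier_factory()
            clf.fit(X[train], y[train])
            pred = np.asarray(clf.predict(X[test]))
            correct += int(np.sum(pred == y[test]))
            fold_cm = _aligned_confusion(y[test], pred, classes)
            pooled = pooled.add(fold_cm)
            if per_class_mode == "averaged":
                fold_reports.append(class_metrics(fold_cm))
        run_accs.append(correct / X.shape[0])

    report = class_metrics(pooled)
    if per_class_mode == "averaged":
        for cls in classes:
            for key in ("precision", "recall", "f1"):
                report.per_class[cls][key] = float(
                    np.mean([fr.per_class[cls][key] for fr in fold_reports])
                )
        report.macro_precision = float(
            np.mean([fr.macro_precision for fr in fold_reports])
        )
        report.macro_recall = float(np.mean([fr.macro_recall for fr in fold_reports]))
        report.macro_f1 = float(np.mean([fr.macro_f1 for fr in fold_reports]))
    report.run_accuracies = run_accs
    report.mean_accuracy = float(np.mean(run_accs))
    report.std = run_std(run_accs)
    return report


def _aligned_confusion(truth, predicted, classes) -> ConfusionMatrix:
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(np.asarray(truth).tolist(), np.asarray(predicted).tolist()):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(classes))
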