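"""Classification problems, channel clusters and cross-validated metrics.

Six class mappings cover the clinically interesting contrasts among
controls (CN), mild AD and moderate AD — including the merged "AD"
class and the merged "CN-mild" class — and each can be evaluated on
the whole montage or on one anatomical electrode cluster (the feature
table is simply restricted to that cluster's 38·|channels| columns).

The default protocol is a Random Forest of 100 trees under
stratified 10-fold cross-validation *at the epoch level*: epochs of
one subject may land in both training and test folds, which
optimistically biases accuracy. A subject-grouped CV mode is provided
behind a flag; results from the two modes measure different things
and must not be mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .montage import cluster_channels

__all__ = [
    "PROBLEMS",
    "MetricSet",
    "build_dataset",
    "run_cv",
    "alt_classifiers",
    "cohen_kappa",
    "weighted_precision_f1",
    "metrics_from_confusion",
]

#: The six classification problems: group -> class, ``None`` = excluded.
PROBLEMS: Dict[str, Dict[str, Optional[str]]] = {
    "CN/AD": {"CN": "CN", "mild": "AD", "moderate": "AD"},
    "CN/mild/moderate": {"CN": "CN", "mild": "mild", "moderate": "moderate"},
    "CN/mild": {"CN": "CN", "mild": "mild", "moderate": None},
    "CN/moderate": {"CN": "CN", "mild": None, "moderate": "moderate"},
    "CN-mild/moderate": {"CN": "CN-mild", "mild": "CN-mild",
                         "moderate": "moderate"},
    "mild/moderate": {"CN": None, "mild": "mild", "moderate": "moderate"},
}


@dataclass
class MetricSet:
    """Pooled cross-validation metrics.

    Accuracy and precision are percentages, F1 and kappa fractions
    (matching how such results are conventionally tabulated);
    ``confusion`` is the pooled k x k count matrix over all test folds
    with rows = true classes in ``classes`` order.
    """

    accuracy: float
    precision: float
    f1: float
    kappa: float
    confusion: np.ndarray
    classes: Tuple[str, ...]
    n_epochs: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "f1": self.f1, "kappa": self.kappa,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes), "n_epochs": self.n_epochs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricSet":
        return cls(
            accuracy=d["accuracy"], precision=d["precision"], f1=d["f1"],
            kappa=d["kappa"], confusion=np.asarray(d["confusion"]),
            classes=tuple(d["classes"]), n_epochs=d["n_epochs"],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetricSet):
            return NotImplemented
        return (
            self.accuracy == other.accuracy
            and self.precision == other.precision
            and self.f1 == other.f1
            and self.kappa == other.kappa
            and np.array_equal(self.confusion, other.confusion)
            and self.classes == other.classes
            and self.n_epochs == other.n_epochs
        )


def build_dataset(features: pd.DataFrame, problem: str,
                  cluster: str = "whole") -> Tuple[pd.DataFrame, pd.Series]:
    """Relabel and filter a feature table for one problem and cluster.

    Returns ``(X, y)``: feature columns restricted to the cluster's
    channels, rows restricted to the problem's classes, labels mapped
    per the problem definition.
    """
    if features.empty:
        raise ValueError("empty feature table")
    class_map = PROBLEMS.get(problem)
    if class_map is None:
        raise KeyError(f"unknown problem {problem!r}; one of {sorted(PROBLEMS)}")
    y = features["label"].map(lambda g: class_map.get(g))
    keep = y.notna()
    if not keep.any():
        raise ValueError(f"no epochs left for problem {problem!r}")
    chans = cluster_channels(cluster)
    cols = [c for c in features.columns
            if "_" in c and c.split("_", 1)[0] in chans]
    X = features.loc[keep, cols]
    y = y[keep]
    if y.nunique() < len(set(v for v in class_map.values() if v)):
        raise ValueError(f"a class of problem {problem!r} has no epochs")
    return X, y


def _make_model(model: str, seed: int, n_trees: int = 100):
    """Model registry for the alternate-classifier comparison."""
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    registry = {
        "RF": lambda: RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "KNN": lambda: KNeighborsClassifier(n_neighbors=1),
        "NB": lambda: GaussianNB(),
        "SVM": lambda: make_pipeline(StandardScaler(),
                                     SVC(random_state=seed)),
        "MLP": lambda: make_pipeline(
            StandardScaler(),
            MLPClassifier(random_state=seed, max_iter=500)),
    }
    if model not in registry:
        raise KeyError(f"unknown model {model!r}; one of {sorted(registry)}")
    return registry[model]()


def run_cv(X: pd.DataFrame, y: pd.Series, folds: int = 10, seed: int = 0,
           model: str = "RF", n_trees: int = 100,
           groups: Sequence | None = None) -> MetricSet:
    """Stratified k-fold cross-validation with a pooled confusion matrix.

    ``groups`` switches to subject-grouped stratified folds (epochs of
    one subject never straddle a train/test split); the default is the
    epoch-level protocol. Deterministic in ``seed``.
    """
    classes = tuple(sorted(pd.unique(y)))
    counts = y.value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has only {counts.min()} epochs; "
            f"use fewer than {folds} folds")
    Xv = np.asarray(X, dtype=np.float64)
    yv = np.asarray(y)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                        random_state=seed)
        split = splitter.split(Xv, yv, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
        split = splitter.split(Xv, yv)
    for train, test in split:
        clf = _make_model(model, seed, n_trees)
        clf.fit(Xv[train], yv[train])
        pred = clf.predict(Xv[test])
        for t, p in zip(yv[test], pred):
            confusion[class_to_idx[t], class_to_idx[p]] += 1
    return metrics_from_confusion(confusion, classes)


def alt_classifiers(X: pd.DataFrame, y: pd.Series, model: str,
                    folds: int = 10, seed: int = 0) -> MetricSet:
    """Same CV contract as :func:`run_cv` with a pluggable model."""
    return run_cv(X, y, folds=folds, seed=seed, model=model)


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix's marginals.

    kappa = (p_o - p_e) / (1 - p_e) with p_e the sum of products of
    row and column marginal probabilities. When p_e = 1 (all mass in
    one cell) kappa is defined as 0 with a warning.
    """
    c = np.asarray(confusion, dtype=np.float64)
    n = c.sum()
    if n <= 0 or (c < 0).any():
        raise ValueError("confusion matrix must be nonnegative with sum > 0")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) / n) @ (c.sum(axis=0) / n))
    if p_e >= 1.0:
        warnings.warn("degenerate confusion matrix (p_e = 1); kappa := 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def weighted_precision_f1(confusion: np.ndarray) -> Tuple[float, float]:
    """Support-weighted precision (%) and F1 (fraction) from a confusion.

    Per-class precision = column diagonal / column sum and recall =
    diagonal / row sum (0 where the denominator is 0); F1 is their
    harmonic mean; the average weights classes by true-class support.
    """
    c = np.asarray(confusion, dtype=np.float64)
    n = c.sum()
    if n <= 0:
        raise ValueError("confusion matrix sum must be > 0")
    support = c.sum(axis=1)
    pred = c.sum(axis=0)
    diag = np.diag(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred > 0, diag / np.where(pred > 0, pred, 1), 0.0)
        rec = np.where(support > 0, diag / np.where(support > 0, support, 1), 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
    w = support / n
    return float(100.0 * (w * prec).sum()), float((w * f1).sum())


def metrics_from_confusion(confusion: np.ndarray,
                           classes: Tuple[str, ...]) -> MetricSet:
    """Assemble a :class:`MetricSet` from a pooled confusion matrix."""
    c = np.asarray(confusion)
    n = int(c.sum())
    precision, f1 = weighted_precision_f1(c)
    return MetricSet(
        accuracy=float(100.0 * np.trace(c) / n),
        precision=precision,
        f1=f1,
        kappa=cohen_kappa(c),
        confusion=c,
        classes=tuple(classes),
        n_epochs=n,
    )
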