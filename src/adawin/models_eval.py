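"""Classifiers, stratified evaluation, confusion-matrix metrics and RFE.

Five classifiers are compared: a linear-kernel SVM (one-vs-all, prediction
by highest confidence score), k-nearest neighbors with k=8, a Gini decision
tree of unlimited depth, Gaussian naive Bayes, and a 100-tree random
forest.  Evaluation is a single stratified 70/30 holdout; precision,
recall and F1 are derived per class one-vs-rest from the confusion matrix.
Recursive feature elimination iteratively drops the lowest-importance
fraction of features under a random-forest scorer until the top 25% remain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

ALGORITHM_NAMES = ("svm", "knn", "dt", "nb", "rf")


class StratificationError(ValueError):
    """A class has too few rows to be split into train and test."""


class DegenerateTrainingError(ValueError):
    """Training data contains fewer than two classes."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm name, hyperparameter overrides and seed for one classifier."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise ValueError(f"unknown algorithm {self.name!r}; expected one of {ALGORITHM_NAMES}")


def make_classifier(spec: ClassifierSpec) -> BaseEstimator:
    """Instantiate the sklearn estimator behind a spec, defaults pinned."""
    hp = dict(spec.hyperparameters)
    if spec.name == "svm":
        return SVC(
            kernel=hp.pop("kernel", "linear"),
            decision_function_shape="ovr",
            random_state=spec.seed,
            **hp,
        )
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 8), **hp)
    if spec.name == "dt":
        return DecisionTreeClassifier(
            criterion=hp.pop("criterion", "gini"),
            max_depth=hp.pop("max_depth", None),
            random_state=spec.seed,
            **hp,
        )
    if spec.name == "nb":
        return GaussianNB(**hp)
    return RandomForestClassifier(
        n_estimators=hp.pop("n_estimators", 100), random_state=spec.seed, **hp
    )


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 with supports and macro averages."""

    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]

    @property
    def macro_precision(self) -> float:
        return float(np.mean([self.precision[c] for c in self.classes]))

    @property
    def macro_recall(self) -> float:
        return float(np.mean([self.recall[c] for c in self.classes]))

    @property
    def macro_f1(self) -> float:
        return float(np.mean([self.f1[c] for c in self.classes]))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            }
        ).loc[self.classes]


def stratified_split(
    table: FeatureTable, train_frac: float = 0.7, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Per-class random holdout: round(train_frac * n_c) rows to train.

    Every class keeps at least one row on each side; reproducible under
    ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = table.frame["label"].to_numpy()
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in sorted(set(labels.tolist())):
        rows = np.flatnonzero(labels == cls)
        if rows.size < 2:
            raise StratificationError(f"class {cls!r} has {rows.size} row(s); need >= 2 to split")
        n_train = int(round(train_frac * rows.size))
        n_train = min(max(n_train, 1), rows.size - 1)
        perm = rng.permutation(rows)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))

    def subset(idx: np.ndarray) -> FeatureTable:
        return FeatureTable(
            frame=table.frame.iloc[idx].reset_index(drop=True),
            ws=table.ws,
            ss=table.ss,
            registry_hash=table.registry_hash,
        )

    return subset(tr), subset(te)


def _confidence_scores(model: BaseEstimator, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)
    scores = model.decision_function(X)
    if scores.ndim == 1:  # binary: ovr scores for (neg, pos)
        scores = np.column_stack([-scores, scores])
    return scores


def fit_predict(
    spec: ClassifierSpec, train: FeatureTable, test: FeatureTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit a classifier on train and predict test.

    Returns ``(y_pred, classes, scores)`` where ``scores`` is the per-class
    confidence matrix (probabilities, or one-vs-rest decision values for the
    SVM) aligned with ``classes``.
    """
    if train.feature_names != test.feature_names:
        raise ValueError("train and test feature columns differ")
    y_train = train.y
    if len(set(y_train.tolist())) < 2:
        raise DegenerateTrainingError("training data must contain at least 2 classes")
    model = make_classifier(spec)
    model.fit(train.X, y_train)
    scores = _confidence_scores(model, test.X, model.classes_)
    y_pred = model.classes_[np.argmax(scores, axis=1)]
    return y_pred, np.asarray(model.classes_), scores


def confusion_and_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, classes: list[str] | None = None
) -> ClassMetrics:
    """Per-class one-vs-rest precision, recall and F1 from the confusion matrix.

    P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); a zero denominator
    yields 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size == 0:
        raise ValueError("need at least one prediction")
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f1: dict[str, float] = {}
    support: dict[str, int] = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = _safe_ratio(tp, tp + fp, f"precision of {cls!r}")
        r = _safe_ratio(tp, tp + fn, f"recall of {cls!r}")
        precision[cls] = p
        recall[cls] = r
        f1[cls] = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        support[cls] = int(cm[i, :].sum())
    return ClassMetrics(
        classes=list(classes), precision=precision, recall=recall, f1=f1, support=support
    )


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return float(num) / float(den)


def rfe_select(
    table: FeatureTable,
    keep_frac: float = 0.25,
    drop_frac_per_iter: float = 0.10,
    seed: int = 0,
) -> list[str]:
    """Recursive feature elimination under random-forest importance.

    Each iteration fits a forest, scores features by impurity importance and
    drops the bottom ``max(1, floor(drop_frac * current))`` — never past the
    target of ``ceil(keep_frac * F)`` features.  Surviving names are
    returned in their original table order.
    """
    if not 0 < keep_frac < 1:
        raise ValueError("keep_frac must be strictly between 0 and 1")
    names = table.feature_names
    if len(names) < 4:
        raise ValueError("RFE needs at least 4 features")
    target = math.ceil(keep_frac * len(names))
    if target < 1:
        raise ValueError("keep target must be at least 1 feature")
    current = list(names)
    X_all = table.frame[current].to_numpy(dtype=float)
    y = table.y
    col_of = {n: i for i, n in enumerate(names)}
    while len(current) > target:
        rf = RandomForestClassifier(n_estimators=100, random_state=seed)
        cols = [col_of[n] for n in current]
        rf.fit(X_all[:, cols], y)
        importances = rf.feature_importances_
        n_drop = min(max(1, math.floor(drop_frac_per_iter * len(current))), len(current) - target)
        order = np.argsort(importances, kind="stable")  # ascending; ties keep earlier column
        dropped = {current[i] for i in order[:n_drop]}
        current = [n for n in current if n not in dropped]
    return [n for n in names if n in set(current)]


class BehaviorClassifier(BaseEstimator, ClassifierMixin):
    """Thin sklearn-compatible wrapper selecting one of the five algorithms.

    Fits on a plain (X, y); composes with sklearn pipelines and model
    selection.  ``algorithm`` is one of 'svm', 'knn', 'dt', 'nb', 'rf'.
    """

    def __init__(self, algorithm: str = "rf", seed: int = 0, hyperparameters: dict | None = None):
        self.algorithm = algorithm
        self.seed = seed
        self.hyperparameters = hyperparameters

    def fit(self, X, y) -> "BehaviorClassifier":
        spec = ClassifierSpec(
            name=self.algorithm, hyperparameters=self.hyperparameters or {}, seed=self.seed
        )
        self.model_ = make_classifier(spec)
        self.model_.fit(np.asarray(X, dtype=float), np.asarray(y))
        self.classes_ = self.model_.classes_
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Per-class confidence matrix aligned with ``classes_``."""
        return _confidence_scores(self.model_, np.asarray(X, dtype=float), self.classes_)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]
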