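"""Feature-subset selection and classification.

Correlation-based feature selection (CFS) scores a candidate subset S by

    merit(S) = k r̄_cf / sqrt(k + k (k − 1) r̄_ff),      k = |S|

where r̄_cf is the mean feature–class association and r̄_ff the mean
pairwise feature–feature association: subsets highly associated with the
diagnosis but mutually non-redundant score best. Associations are
symmetric uncertainties after equal-frequency discretization into 5 bins
(the class stays categorical). The subset space is explored by forward
best-first search — greedy hill climbing with a backtracking queue,
stopping after a fixed number of consecutive non-improving expansions.

Classification is a one-hidden-layer feedforward network (logistic units,
stochastic gradient descent with momentum), evaluated by stratified k-fold
cross-validation with imputation — and optionally the subset selection —
re-fit inside every training fold so no test-fold information leaks.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .discrimination import roc_curve

CLASS_ORDER = ("CN", "MCI", "MD")


# ----------------------------------------------------------------------
# association provider: symmetric uncertainty on discretized features
# ----------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _discretize(x: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-frequency binning; duplicate quantile edges collapse."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """2·I(A;B) / (H(A)+H(B)) on discrete codes; 0 when both are constant."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    if ha + hb == 0:
        return 0.0
    hab = _entropy(joint.ravel())
    mi = max(ha + hb - hab, 0.0)
    return 2.0 * mi / (ha + hb)


class SymmetricUncertaintyAssoc:
    """Pairwise association provider backed by a feature matrix.

    Feature columns are discretized into ``n_bins`` equal-frequency bins;
    the class labels stay categorical. Associations are cached.
    """

    def __init__(self, X: pd.DataFrame, y: Sequence, n_bins: int = 5):
        self.names = list(X.columns)
        self._codes = {
            c: _discretize(np.asarray(X[c], dtype=float), n_bins) for c in self.names
        }
        self._y = np.asarray(y)
        self._fc: dict[str, float] = {}
        self._ff: dict[frozenset, float] = {}

    def feature_class(self, name: str) -> float:
        if name not in self._fc:
            self._fc[name] = symmetric_uncertainty(self._codes[name], self._y)
        return self._fc[name]

    def feature_feature(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self._ff:
            self._ff[key] = symmetric_uncertainty(self._codes[a], self._codes[b])
        return self._ff[key]


class DictAssoc:
    """Association provider from explicit tables (used for oracles/tests)."""

    def __init__(self, feature_class: dict[str, float], feature_feature: dict):
        self.names = list(feature_class)
        self._fc = dict(feature_class)
        self._ff = {frozenset(k): v for k, v in feature_feature.items()}

    def feature_class(self, name: str) -> float:
        return self._fc[name]

    def feature_feature(self, a: str, b: str) -> float:
        return self._ff.get(frozenset((a, b)), 0.0)


# ----------------------------------------------------------------------
# CFS merit and best-first subset search
# ----------------------------------------------------------------------

def cfs_merit(subset: Sequence[str], assoc) -> float:
    """CFS merit of a feature subset; 0 for the empty set by convention."""
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = float(np.mean([assoc.feature_class(f) for f in subset]))
    if k == 1:
        r_ff = 0.0
    else:
        r_ff = float(np.mean([assoc.feature_feature(a, b) for a, b in combinations(subset, 2)]))
    return k * r_cf / math.sqrt(k + k * (k - 1) * r_ff)


@dataclass
class SelectionResult:
    selected: list[str]
    merit: float
    n_evaluated: int


def best_first_select(
    features: Sequence[str], assoc, stale_limit: int = 5
) -> SelectionResult:
    """Forward best-first search over feature subsets by CFS merit.

    Starts from the empty set; repeatedly expands the highest-merit
    unexpanded subset by all single-feature additions, keeping a priority
    queue of frontier nodes. Stops after ``stale_limit`` consecutive
    expansions that fail to improve the best merit seen, or when the
    frontier is exhausted. Ties are broken lexicographically on the sorted
    feature names, so the result is deterministic.
    """
    if len(features) == 0:
        raise ValueError("need at least one candidate feature")
    names = sorted(features)
    evaluated: dict[frozenset, float] = {}

    def merit_of(s: frozenset) -> float:
        if s not in evaluated:
            evaluated[s] = cfs_merit(sorted(s), assoc)
        return evaluated[s]

    empty = frozenset()
    best_set, best_merit = empty, merit_of(empty)
    # heap orders by (-merit, sorted-name tuple) -> deterministic
    frontier: list[tuple[float, tuple[str, ...], frozenset]] = []
    heapq.heappush(frontier, (-best_merit, tuple(sorted(empty)), empty))
    in_frontier = {empty}
    stale = 0

    while frontier and stale < stale_limit:
        _, _, node = heapq.heappop(frontier)
        in_frontier.discard(node)
        improved = False
        for f in names:
            if f in node:
                continue
            child = node | {f}
            seen = child in evaluated
            m = merit_of(child)
            if m > best_merit + 1e-12:
                best_merit, best_set = m, child
                improved = True
            if not seen and child not in in_frontier:
                heapq.heappush(frontier, (-m, tuple(sorted(child)), child))
                in_frontier.add(child)
        stale = 0 if improved else stale + 1

    return SelectionResult(
        selected=sorted(best_set), merit=best_merit, n_evaluated=len(evaluated)
    )


def exhaustive_select(features: Sequence[str], assoc) -> SelectionResult:
    """Brute-force best subset over all 2^d − 1 candidates (oracle)."""
    names = sorted(features)
    best_set: tuple[str, ...] = ()
    best_merit = 0.0
    n = 0
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            n += 1
            m = cfs_merit(subset, assoc)
            if m > best_merit + 1e-12:
                best_merit, best_set = m, subset
    return SelectionResult(selected=list(best_set), merit=best_merit, n_evaluated=n)


# ----------------------------------------------------------------------
# classifier and cross-validated report
# ----------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    hidden_units: Optional[int] = None  # default ceil((n_features + n_classes)/2)
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    seed: int = 0


@dataclass
class ClassifierReport:
    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = true class, cols = predicted
    tp_rate: dict[str, float]
    fp_rate: dict[str, float]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    roc_area: dict[str, float]
    overall_accuracy: float  # percent
    selected_features: list[list[str]] = field(default_factory=list)
    #: pooled out-of-fold class probabilities, rows aligned with the input
    oof_proba: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": {
                c: {
                    "tp_rate": self.tp_rate[c],
                    "fp_rate": self.fp_rate[c],
                    "sensitivity": self.sensitivity[c],
                    "specificity": self.specificity[c],
                    "roc_area": self.roc_area[c],
                }
                for c in self.classes
            },
            "overall_accuracy": self.overall_accuracy,
            "selected_features": self.selected_features,
        }


def train_classifier(
    X: np.ndarray, y: Sequence, config: ClassifierConfig | None = None
) -> Pipeline:
    """Fit the feedforward network on a complete-feature matrix.

    One hidden layer of logistic units (default size
    ``ceil((n_features + n_classes)/2)``), trained by seeded SGD with
    momentum on z-standardized inputs; exposes ``predict_proba``.
    """
    config = config or ClassifierConfig()
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    X = np.asarray(X, dtype=float)
    hidden = config.hidden_units or math.ceil((X.shape[1] + classes.size) / 2)
    model = Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean")),
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(hidden,),
                    activation="logistic",
                    solver="sgd",
                    learning_rate="constant",
                    learning_rate_init=config.learning_rate,
                    momentum=config.momentum,
                    nesterovs_momentum=False,
                    alpha=0.0,
                    max_iter=config.epochs,
                    n_iter_no_change=config.epochs,
                    tol=0.0,
                    random_state=config.seed,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        # fixed-epoch training: the SGD loop is meant to run all epochs
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        model.fit(X, y)
    return model


def cross_validate(
    X: pd.DataFrame,
    y: Sequence,
    k: int = 10,
    seed: int = 0,
    selection: str = "nested",
    stale_limit: int = 5,
    config: ClassifierConfig | None = None,
    classes: Sequence[str] | None = None,
) -> ClassifierReport:
    """Stratified k-fold cross-validated classification report.

    ``selection``: ``"nested"`` re-runs CFS/best-first inside each training
    fold (leakage-free, the default); ``"pooled"`` selects once on all data
    before cross-validation (comparable to a single published feature
    ranking, optimistic); ``"none"`` uses every feature. Imputation (train-
    fold means) and input standardization are always fold-internal. Pooled
    out-of-fold predictions fill the confusion matrix; per-class ROC areas
    are one-vs-rest trapezoidal AUCs of the out-of-fold probabilities.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if selection not in ("nested", "pooled", "none"):
        raise ValueError(f"unknown selection mode: {selection!r}")
    y = np.asarray(y)
    if classes is None:
        classes = tuple(c for c in CLASS_ORDER if c in set(y)) or tuple(np.unique(y))
    classes = tuple(classes)
    config = config or ClassifierConfig(seed=seed)

    feature_cols = list(X.columns)
    if selection == "pooled":
        assoc = SymmetricUncertaintyAssoc(_impute_frame(X), y)
        pooled_sel = best_first_select(feature_cols, assoc, stale_limit).selected
    else:
        pooled_sel = None

    oof_proba = np.full((len(y), len(classes)), np.nan)
    selected_per_fold: list[list[str]] = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        X_tr = _impute_frame(X.iloc[train_idx])
        if selection == "nested":
            assoc = SymmetricUncertaintyAssoc(X_tr, y[train_idx])
            cols = best_first_select(feature_cols, assoc, stale_limit).selected or feature_cols
        elif selection == "pooled":
            cols = pooled_sel or feature_cols
        else:
            cols = feature_cols
        selected_per_fold.append(list(cols))
        means = X_tr[cols].mean()
        X_te = X.iloc[test_idx][cols].fillna(means)
        model = train_classifier(X_tr[cols].to_numpy(), y[train_idx], config)
        proba = model.predict_proba(X_te.to_numpy())
        model_classes = list(model.classes_)
        for j, c in enumerate(classes):
            if c in model_classes:
                oof_proba[test_idx, j] = proba[:, model_classes.index(c)]
            else:
                oof_proba[test_idx, j] = 0.0

    pred = np.asarray(classes)[np.argmax(oof_proba, axis=1)]
    report = build_report(y, pred, oof_proba, classes, selected_per_fold)
    report.oof_proba = oof_proba
    return report


def _impute_frame(X: pd.DataFrame) -> pd.DataFrame:
    return X.fillna(X.mean())


def build_report(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    proba: np.ndarray,
    classes: tuple[str, ...],
    selected: list[list[str]] | None = None,
) -> ClassifierReport:
    """Confusion matrix and per-class rates from pooled predictions."""
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[idx[t], idx[p]] += 1
    total = confusion.sum()
    tp_rate, fp_rate, sens, spec, auc = {}, {}, {}, {}, {}
    for c in classes:
        i = idx[c]
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        tp_rate[c] = tp / (tp + fn) if tp + fn else 0.0
        fp_rate[c] = fp / (fp + tn) if fp + tn else 0.0
        sens[c] = tp_rate[c]
        spec[c] = 1.0 - fp_rate[c]
        auc[c] = roc_curve(proba[:, i], (y_true == c).astype(int)).auc
    return ClassifierReport(
        classes=classes,
        confusion=confusion,
        tp_rate=tp_rate,
        fp_rate=fp_rate,
        sensitivity=sens,
        specificity=spec,
        roc_area=auc,
        overall_accuracy=100.0 * np.trace(confusion) / total,
        selected_features=selected or [],
    )
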