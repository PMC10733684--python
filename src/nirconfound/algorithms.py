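"""The nine classifier families with their fixed study hyperparameters.

Every algorithm is exposed through one uniform contract: ``make_algorithm``
builds an immutable spec, ``fit`` trains it, ``predict_scores`` returns a
real-valued score per row (higher = more positive-class).  Hyperparameters
are pinned: AdaBoost 50 estimators / learning rate 1; gradient boosting 100
trees / rate 0.1 / depth 3 / min-split 2; kNN k=7 Euclidean uniform;
ridge-penalised logistic regression C=1; Gaussian naive Bayes; a 100-neuron
ReLU/Adam network capped at 200 iterations; random forest of 10 trees with
min-split 5; an RBF SVM with cost 1, tolerance 1e-3 and a 100-iteration cap;
and a depth-10 decision tree (min-split 5) that additionally stops splitting
any node whose majority class reaches 95%.  Knobs not fixed by the study are
left at scikit-learn defaults and recorded in the ``algorithms.lock`` report
so runs are reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.tree._tree import TREE_LEAF

__all__ = [
    "ALGORITHM_NAMES",
    "AlgorithmSpec",
    "FittedModel",
    "make_algorithm",
    "fit",
    "predict_scores",
    "algorithm_lock_report",
]

ALGORITHM_NAMES = (
    "AdaBoost",
    "GradientBoosting",
    "kNN",
    "LogisticRegression",
    "NaiveBayes",
    "NeuralNetwork",
    "RandomForest",
    "SVM",
    "Tree",
)

#: Node-purity threshold at which the decision tree stops splitting.
TREE_MAJORITY_STOP = 0.95


class AlgorithmError(ValueError):
    pass


_HYPERPARAMETERS: dict[str, dict] = {
    "AdaBoost": {"n_estimators": 50, "learning_rate": 1.0},
    "GradientBoosting": {
        "n_estimators": 100,
        "learning_rate": 0.1,
        "max_depth": 3,
        "min_samples_split": 2,
    },
    "kNN": {"n_neighbors": 7, "metric": "euclidean", "weights": "uniform"},
    # ridge (L2) penalty is the sklearn default; only C is pinned
    "LogisticRegression": {"C": 1.0, "max_iter": 1000},
    "NaiveBayes": {},
    "NeuralNetwork": {
        "hidden_layer_sizes": (100,),
        "activation": "relu",
        "solver": "adam",
        "max_iter": 200,
    },
    "RandomForest": {"n_estimators": 10, "min_samples_split": 5},
    "SVM": {"C": 1.0, "kernel": "rbf", "tol": 0.001, "max_iter": 100},
    "Tree": {
        "max_depth": 10,
        "min_samples_split": 5,
        "majority_stop": TREE_MAJORITY_STOP,
    },
}

_SEEDED = {"AdaBoost", "GradientBoosting", "LogisticRegression", "NeuralNetwork",
           "RandomForest", "Tree"}


@dataclass(frozen=True)
class AlgorithmSpec:
    """Immutable (name, hyperparameters, seed) triple."""

    name: str
    hyperparameters: Mapping
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hyperparameters", MappingProxyType(dict(self.hyperparameters)))


@dataclass
class FittedModel:
    spec: AlgorithmSpec
    estimator: object
    n_channels: int
    classes: tuple = (0, 1)


def make_algorithm(name: str, seed: int = 0) -> AlgorithmSpec:
    """Spec for one of the nine algorithm families, at the fixed settings."""
    if name not in ALGORITHM_NAMES:
        raise AlgorithmError(
            f"unknown algorithm {name!r}; valid names: {', '.join(ALGORITHM_NAMES)}"
        )
    return AlgorithmSpec(name=name, hyperparameters=_HYPERPARAMETERS[name], seed=seed)


def _build_estimator(spec: AlgorithmSpec):
    hp = dict(spec.hyperparameters)
    if spec.name == "AdaBoost":
        return AdaBoostClassifier(random_state=spec.seed, **hp)
    if spec.name == "GradientBoosting":
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.name == "kNN":
        return KNeighborsClassifier(**hp)
    if spec.name == "LogisticRegression":
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.name == "NaiveBayes":
        return GaussianNB(**hp)
    if spec.name == "NeuralNetwork":
        return MLPClassifier(random_state=spec.seed, **hp)
    if spec.name == "RandomForest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.name == "SVM":
        return SVC(**hp)
    if spec.name == "Tree":
        hp.pop("majority_stop")
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    raise AlgorithmError(spec.name)  # pragma: no cover


def _prune_majority(tree, threshold: float) -> None:
    """Collapse any node whose majority class fraction reaches the threshold."""
    t = tree.tree_
    for node in range(t.node_count):
        if t.children_left[node] == TREE_LEAF:
            continue
        counts = t.value[node][0]
        if counts.max() / counts.sum() >= threshold:
            t.children_left[node] = TREE_LEAF
            t.children_right[node] = TREE_LEAF


def fit(spec: AlgorithmSpec, X, y) -> FittedModel:
    """Train the spec on a samples x channels matrix with binary labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise AlgorithmError("X must be 2-D with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise AlgorithmError("training labels contain a single class")
    if counts.min() < 2:
        raise AlgorithmError("each class needs >= 2 training samples")
    if not np.all(np.isfinite(X)):
        raise AlgorithmError("training matrix contains non-finite values")
    est = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    if spec.name == "Tree":
        _prune_majority(est, spec.hyperparameters["majority_stop"])
    return FittedModel(spec=spec, estimator=est, n_channels=X.shape[1],
                       classes=tuple(classes))


def predict_scores(m: FittedModel, X) -> np.ndarray:
    """Positive-class score per row: probability where the model defines one,
    signed margin for the SVM."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != m.n_channels:
        raise AlgorithmError(
            f"expected {m.n_channels} channels, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    est = m.estimator
    if isinstance(est, SVC):
        scores = est.decision_function(X)
    else:
        pos_col = int(np.flatnonzero(np.asarray(est.classes_) == m.classes[-1])[0])
        scores = est.predict_proba(X)[:, pos_col]
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise AlgorithmError("model produced non-finite scores")
    return scores


def predict_labels(m: FittedModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != m.n_channels:
        raise AlgorithmError(f"expected {m.n_channels} channels")
    return np.asarray(m.estimator.predict(X)).astype(int)


def algorithm_lock_report(seed: int = 0, names=ALGORITHM_NAMES) -> str:
    """Full resolved parameter dump (fixed + ecosystem defaults) per algorithm.

    Written alongside run artifacts so every unpinned knob is on record.
    """
    report = {}
    for name in names:
        spec = make_algorithm(name, seed=seed)
        est = _build_estimator(spec)
        params = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in sorted(est.get_params().items())
            if not callable(v)
        }
        if name == "Tree":
            params["majority_stop"] = TREE_MAJORITY_STOP
        report[name] = params
    return json.dumps(report, indent=2, default=str)
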