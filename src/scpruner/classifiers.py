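"""Classifier bank: six region-delineation principles behind one contract.

Every classifier exposes fit / predict / predict_proba on a common label
universe.  Kinds without native probabilities (the two max-margin kinds)
return a softmax over their decision values, which is monotone in the
decision score — sufficient for confidence-based rejection.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.special import softmax
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC

from .exceptions import DegenerateDataError, ValidationError
from .matrix import LabelVector


class ClassifierKind(enum.Enum):
    bayes = "bayes"
    linear_margin = "linear_margin"
    rbf_margin = "rbf_margin"
    neighbor = "neighbor"
    forest_vote = "forest_vote"
    multilayer = "multilayer"


#: Fixed enumeration order of the classifier bank.
CLASSIFIER_ORDER: tuple[ClassifierKind, ...] = (
    ClassifierKind.bayes,
    ClassifierKind.linear_margin,
    ClassifierKind.rbf_margin,
    ClassifierKind.neighbor,
    ClassifierKind.forest_vote,
    ClassifierKind.multilayer,
)

#: Kinds whose predict is exactly the row argmax of predict_proba.
CALIBRATED_KINDS = frozenset({
    ClassifierKind.bayes,
    ClassifierKind.neighbor,
    ClassifierKind.forest_vote,
    ClassifierKind.multilayer,
})

DEFAULT_PARAMS: dict[str, Any] = {
    "bayes_alpha": 1.0,
    "margin_C": 1.0,
    "rbf_gamma": "scale",
    "n_neighbors": 5,
    "n_trees": 100,
    "hidden_units": 100,
    "max_epochs": 200,
}


@dataclass
class FittedClassifier:
    kind: ClassifierKind
    categories: list[str]
    model: Any
    seed: int
    n_features: int


def _build(kind: ClassifierKind, seed: int, params: dict[str, Any]):
    p = {**DEFAULT_PARAMS, **(params or {})}
    if kind is ClassifierKind.bayes:
        return MultinomialNB(alpha=p["bayes_alpha"])
    if kind is ClassifierKind.linear_margin:
        # one-vs-rest: one hyperplane per class
        return LinearSVC(C=p["margin_C"], random_state=seed)
    if kind is ClassifierKind.rbf_margin:
        # one-vs-one training with summed votes; ovr-shaped decision values
        return SVC(kernel="rbf", C=p["margin_C"], gamma=p["rbf_gamma"],
                   decision_function_shape="ovr", random_state=seed)
    if kind is ClassifierKind.neighbor:
        return KNeighborsClassifier(n_neighbors=p["n_neighbors"])
    if kind is ClassifierKind.forest_vote:
        return RandomForestClassifier(n_estimators=p["n_trees"], random_state=seed)
    if kind is ClassifierKind.multilayer:
        return MLPClassifier(hidden_layer_sizes=(p["hidden_units"],),
                             max_iter=p["max_epochs"], random_state=seed)
    raise ValueError(f"unknown classifier kind: {kind}")


def fit(kind: ClassifierKind, X: np.ndarray, y: LabelVector, seed: int = 0,
        params: dict[str, Any] | None = None) -> FittedClassifier:
    """Fit one classifier; convergence shortfalls are kept as best-effort fits."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != len(y.labels):
        raise ValidationError("X rows must match the number of labels")
    present = sorted(set(y.labels.tolist()))
    if len(present) < 2:
        raise DegenerateDataError("training labels contain a single class")
    if kind is ClassifierKind.bayes and np.any(X < 0):
        raise ValidationError("bayes requires non-negative features")
    model = _build(kind, seed, params or {})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, np.asarray(y.labels, dtype=object))
    categories = [str(c) for c in model.classes_]
    return FittedClassifier(kind, categories, model, seed, X.shape[1])


def _check_X(fc: FittedClassifier, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != fc.n_features:
        raise ValidationError(
            f"expected {fc.n_features} features, got {X.shape[1] if X.ndim == 2 else X.ndim}"
        )
    return X


def predict_proba(fc: FittedClassifier, X: np.ndarray) -> np.ndarray:
    """Class probabilities (cells x k); rows sum to one."""
    X = _check_X(fc, X)
    if fc.kind in CALIBRATED_KINDS:
        return fc.model.predict_proba(X)
    scores = fc.model.decision_function(X)
    if scores.ndim == 1:  # binary: single signed margin
        scores = np.column_stack([-scores, scores])
    return softmax(scores, axis=1)


def predict(fc: FittedClassifier, X: np.ndarray) -> np.ndarray:
    """Predicted labels; for calibrated kinds exactly argmax of predict_proba."""
    X = _check_X(fc, X)
    if fc.kind in CALIBRATED_KINDS:
        proba = predict_proba(fc, X)
        cats = np.asarray(fc.categories, dtype=object)
        return cats[np.argmax(proba, axis=1)]
    return np.asarray(fc.model.predict(X), dtype=object)
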