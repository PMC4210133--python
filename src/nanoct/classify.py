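"""Seven classifier families behind one train/score/predict contract.

Families (binary classification, positive class = ``nano``):

``mnb``         multinomial naive Bayes with additive smoothing alpha;
                accepts real-valued nonnegative features so tf-idf inputs
                are supported
``c45``         decision tree grown on the information-gain (entropy)
                criterion, the CART analogue of the classic C4.5 tree
``sgd_logreg``  logistic regression fit by stochastic gradient descent
``l1_logreg``   lasso-penalized logistic regression
``l2_logreg``   ridge-penalized logistic regression
``svm_linear``  soft-margin SVM, linear kernel
``svm_poly2``   soft-margin SVM, polynomial kernel of degree 2

The module owns the contract — hyperparameter surface, determinism under a
seed, score orientation (higher = more nano-like) and the tie rule
(score exactly at threshold predicts the positive class).  The convex
optimization itself is delegated to scikit-learn solvers.

Scores: the logistic families, the naive Bayes and the tree return a
positive-class probability in [0, 1] (decision threshold 0.5); the SVMs
return a signed margin (threshold 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .vectorize import DocTermMatrix

__all__ = ["FAMILIES", "ClassifierSpec", "TrainedModel", "train", "score",
           "predict", "save_model", "load_model"]

FAMILIES = (
    "mnb", "c45", "sgd_logreg", "l1_logreg", "l2_logreg",
    "svm_linear", "svm_poly2",
)

_MARGIN_FAMILIES = {"svm_linear", "svm_poly2"}
_LINEAR_FAMILIES = {"sgd_logreg", "l1_logreg", "l2_logreg", "svm_linear"}


@dataclass(frozen=True)
class ClassifierSpec:
    """Family, hyperparameters and seed.

    Hyperparameters (defaults chosen to be mild; all overridable):

    - ``lam``: regularization strength for the logistic families
      (penalty weight; the solver cost is C = 1/lam), default 1.0
    - ``C``: SVM cost, default 1.0
    - ``alpha``: MNB additive smoothing, default 1.0
    - ``sgd_epochs``: SGD passes over the data, default 100
    - ``min_leaf``: tree minimum samples per leaf, default 2
    """

    family: str
    lam: float = 1.0
    C: float = 1.0
    alpha: float = 1.0
    sgd_epochs: int = 100
    min_leaf: int = 2
    seed: int = 0
    positive_label: str = "nano"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if min(self.lam, self.C, self.alpha) <= 0:
            raise ValueError("lam, C and alpha must be positive")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    classes: tuple[str, str]          # (positive, negative)

    @property
    def threshold(self) -> float:
        return 0.0 if self.spec.family in _MARGIN_FAMILIES else 0.5

    @property
    def coef_(self) -> np.ndarray:
        """Weight vector oriented toward the positive class (linear families)."""
        if self.spec.family not in _LINEAR_FAMILIES:
            raise AttributeError(f"{self.spec.family} exposes no weight vector")
        w = np.asarray(self.estimator.coef_).ravel()
        return w * self._sign

    @property
    def intercept_(self) -> float:
        if self.spec.family not in _LINEAR_FAMILIES:
            raise AttributeError(f"{self.spec.family} exposes no intercept")
        return float(np.asarray(self.estimator.intercept_).ravel()[0]) * self._sign

    @property
    def _sign(self) -> float:
        # sklearn orients decision values toward estimator.classes_[1]
        return 1.0 if self.estimator.classes_[1] == self.spec.positive_label else -1.0


def _build_estimator(spec: ClassifierSpec):
    if spec.family == "mnb":
        return MultinomialNB(alpha=spec.alpha)
    if spec.family == "c45":
        return DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=spec.min_leaf,
            random_state=spec.seed,
        )
    if spec.family == "sgd_logreg":
        return SGDClassifier(
            loss="log_loss",
            alpha=spec.lam / 100.0,
            max_iter=spec.sgd_epochs,
            tol=1e-4,
            random_state=spec.seed,
        )
    if spec.family == "l1_logreg":
        return LogisticRegression(
            l1_ratio=1.0, C=1.0 / spec.lam, solver="liblinear",
            random_state=spec.seed,
        )
    if spec.family == "l2_logreg":
        return LogisticRegression(
            l1_ratio=0.0, C=1.0 / spec.lam, solver="liblinear",
            random_state=spec.seed,
        )
    if spec.family == "svm_linear":
        return SVC(kernel="linear", C=spec.C, random_state=spec.seed)
    if spec.family == "svm_poly2":
        return SVC(kernel="poly", degree=2, gamma=1.0, coef0=0.0,
                   C=spec.C, random_state=spec.seed)
    raise ValueError(spec.family)  # unreachable


def _as_matrix(X) -> sp.csr_matrix:
    if isinstance(X, DocTermMatrix):
        return X.matrix
    return sp.csr_matrix(X)


def train(matrix: DocTermMatrix | sp.spmatrix, labels: Sequence[str],
          spec: ClassifierSpec) -> TrainedModel:
    """Fit one classifier; deterministic given (matrix, labels, spec.seed)."""
    X = _as_matrix(matrix)
    y = np.asarray(labels)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training documents")
    uniq = sorted(set(y))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 classes, got {uniq}")
    if spec.positive_label not in uniq:
        raise ValueError(f"positive label {spec.positive_label!r} absent from labels")
    if spec.family == "mnb" and X.data.size and X.data.min() < 0:
        raise ValueError("multinomial naive Bayes requires nonnegative features")
    est = _build_estimator(spec)
    est.fit(X, y)
    negative = next(c for c in uniq if c != spec.positive_label)
    return TrainedModel(spec=spec, estimator=est,
                        classes=(spec.positive_label, negative))


def score(model: TrainedModel, X) -> np.ndarray:
    """Positive-class score per row; higher = more nano-like."""
    X = _as_matrix(X)
    expected = model.estimator.n_features_in_
    if X.shape[1] != expected:
        raise ValueError(
            f"feature dimension {X.shape[1]} != training dimension {expected}"
        )
    if model.spec.family in _MARGIN_FAMILIES:
        return np.asarray(model.estimator.decision_function(X)).ravel() * model._sign
    proba = model.estimator.predict_proba(X)
    pos_col = list(model.estimator.classes_).index(model.spec.positive_label)
    return proba[:, pos_col]


def predict(model: TrainedModel, X, threshold: float | None = None) -> np.ndarray:
    """Thresholded hard labels; a score exactly at threshold goes positive."""
    s = score(model, X)
    if threshold is None:
        threshold = model.threshold
    pos, neg = model.classes
    return np.where(s >= threshold, pos, neg)


def save_model(model: TrainedModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump({"format_version": 1, "spec": model.spec,
                 "estimator": model.estimator, "classes": model.classes},
                directory / "model.joblib")


def load_model(directory: str | Path) -> TrainedModel:
    payload = joblib.load(Path(directory) / "model.joblib")
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model format")
    return TrainedModel(spec=payload["spec"], estimator=payload["estimator"],
                        classes=payload["classes"])
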