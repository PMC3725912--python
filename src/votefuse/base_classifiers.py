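"""Uniform train/predict contract over the five base classifier families.

Methods: ``lda``, ``svm_linear``, ``svm_poly``, ``svm_rbf``, ``nbc``
(Gaussian naive Bayes) and ``dt`` (CART).  Hyperparameters are frozen at the
documented defaults below and recorded in run metadata, rather than tracking
any one ecosystem's drifting defaults:

* SVM: cost C=1; RBF gamma = 1/n_features; polynomial degree 3,
  gamma = 1/n_features, coef0 = 0;
* LDA: class priors proportional to training counts (equal under balanced
  subsampling); pooled covariance with a 1e-8 ridge so collinear or constant
  features warn instead of crash;
* NBC: per-feature Gaussian class-conditionals (normalized genotypes are
  treated as continuous);
* DT: Gini impurity, min node size to split 20, cost-complexity pruning
  alpha 0.01.

Predictions are hard labels only; a decision score exactly on the boundary
is called negative (control) — conservative and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io_model import CASE, CONTROL, ValidationError

METHODS = ("lda", "svm_linear", "svm_poly", "svm_rbf", "nbc", "dt")

_POSITIVE = 1  # internal integer code for the case class
_NEGATIVE = 0


def default_hyperparameters(method: str, n_features: int) -> dict[str, Any]:
    """The frozen default hyperparameter table for one method."""
    if method == "lda":
        return {"solver": "lsqr", "shrinkage": 1e-8}
    if method == "svm_linear":
        return {"kernel": "linear", "C": 1.0}
    if method == "svm_poly":
        return {"kernel": "poly", "C": 1.0, "degree": 3,
                "gamma": 1.0 / n_features, "coef0": 0.0}
    if method == "svm_rbf":
        return {"kernel": "rbf", "C": 1.0, "gamma": 1.0 / n_features}
    if method == "nbc":
        return {}
    if method == "dt":
        return {"criterion": "gini", "min_samples_split": 20, "ccp_alpha": 0.01}
    raise ValidationError(f"unknown classifier {method!r}; choose from {METHODS}")


@dataclass
class BaseClassifierSpec:
    method: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown classifier {self.method!r}; choose from {METHODS}"
            )

    def filled(self, n_features: int) -> dict[str, Any]:
        hp = default_hyperparameters(self.method, n_features)
        hp.update(self.hyperparameters)
        return hp


@dataclass
class FittedPredictor:
    spec: BaseClassifierSpec
    estimator: Any
    feature_names: list[str]
    uses_decision_function: bool

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self, X)


def _make_estimator(spec: BaseClassifierSpec, n_features: int, seed: int):
    hp = spec.filled(n_features)
    if spec.method == "lda":
        return LinearDiscriminantAnalysis(**hp), True
    if spec.method.startswith("svm"):
        return SVC(**hp), True
    if spec.method == "nbc":
        return GaussianNB(**hp), False
    return DecisionTreeClassifier(random_state=seed, **hp), False


def train(
    spec: BaseClassifierSpec | str,
    X: pd.DataFrame,
    y,
    seed: int = 0,
) -> FittedPredictor:
    """Fit one base classifier on a feature frame and case/control labels."""
    if isinstance(spec, str):
        spec = BaseClassifierSpec(spec)
    X = pd.DataFrame(X)
    arr = X.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("training features contain non-finite values")
    y_int = np.asarray(
        [_POSITIVE if lbl == CASE else _NEGATIVE for lbl in np.asarray(y)]
    )
    if len(set(y_int)) < 2:
        raise ValidationError("training labels contain a single class")
    est, uses_df = _make_estimator(spec, X.shape[1], seed)
    est.fit(arr, y_int)
    return FittedPredictor(spec, est, list(X.columns), uses_df)


def predict(model: FittedPredictor, X: pd.DataFrame) -> np.ndarray:
    """Hard case/control labels; boundary ties resolve to control."""
    X = pd.DataFrame(X)
    if list(X.columns) != model.feature_names:
        raise ValidationError(
            f"feature mismatch: model trained on {model.feature_names}, "
            f"given {list(X.columns)}"
        )
    arr = X.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("prediction features contain non-finite values")
    if model.uses_decision_function:
        # classes_ is [0, 1]; positive score favors the case class
        score = model.estimator.decision_function(arr)
        pos = score > 0
    else:
        proba = model.estimator.predict_proba(arr)
        pos_col = list(model.estimator.classes_).index(_POSITIVE)
        pos = proba[:, pos_col] > 0.5
    return np.where(pos, CASE, CONTROL)
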