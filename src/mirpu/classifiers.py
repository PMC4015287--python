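"""Pluggable probabilistic base classifiers.

The ensemble only requires the small contract below: ``fit`` accepting
optional per-example misclassification costs, and ``predict_prob``
returning values in [0, 1].  Any classifier with those properties can be
plugged in; two implementations are provided.

- :class:`CalibratedSVC` — the default: an RBF-kernel margin classifier
  with sigmoid (Platt-style) probability calibration, C = 1 and kernel
  width 1/s.  Margin classifiers are robust to the heavy redundancy
  (collinearity) among target-prediction scores, and the sigmoid fit turns
  decision values into posterior probabilities.
- :class:`LogisticBase` — an L2-regularised logistic regression; much
  faster on large tables, well suited to property testing and to score
  panels whose class-conditional distributions are roughly Gaussian.
"""

from __future__ import annotations

from typing import Callable, Protocol, runtime_checkable

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["ProbabilisticClassifier", "CalibratedSVC", "LogisticBase", "base_factory"]


@runtime_checkable
class ProbabilisticClassifier(Protocol):
    def fit(self, X, y, sample_weight=None) -> "ProbabilisticClassifier": ...

    def predict_prob(self, X) -> np.ndarray: ...


def _proba_of_class1(est, X) -> np.ndarray:
    """predict_proba column for class 1, robust to class ordering."""
    proba = est.predict_proba(X)
    idx = int(np.flatnonzero(est.classes_ == 1)[0])
    return np.clip(proba[:, idx], 0.0, 1.0)


class CalibratedSVC:
    """RBF SVC with cross-validated Platt (sigmoid) probability calibration."""

    def __init__(
        self,
        C: float = 1.0,
        gamma="auto",
        random_state: int | None = 0,
        cv: int = 5,
    ):
        # gamma="auto" is 1 / n_features
        self.C = C
        self.gamma = gamma
        self.random_state = random_state
        self.cv = cv
        self._est = None

    def fit(self, X, y, sample_weight=None):
        svc = SVC(C=self.C, kernel="rbf", gamma=self.gamma,
                  random_state=self.random_state)
        cv = StratifiedKFold(n_splits=self.cv, shuffle=True,
                             random_state=self.random_state)
        self._est = CalibratedClassifierCV(svc, method="sigmoid", cv=cv,
                                           ensemble=False)
        self._est.fit(X, y, sample_weight=sample_weight)
        return self

    def predict_prob(self, X) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("classifier is not fitted")
        return _proba_of_class1(self._est, X)


class LogisticBase:
    """L2-regularised logistic regression (lbfgs), natively probabilistic."""

    def __init__(self, C: float = 1.0, random_state: int | None = 0):
        self.C = C
        self.random_state = random_state
        self._est: LogisticRegression | None = None

    def fit(self, X, y, sample_weight=None):
        self._est = LogisticRegression(C=self.C, max_iter=2000)
        self._est.fit(X, y, sample_weight=sample_weight)
        return self

    def predict_prob(self, X) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("classifier is not fitted")
        return _proba_of_class1(self._est, X)


def base_factory(name: str = "svc", **kwargs) -> Callable[[int], ProbabilisticClassifier]:
    """Return a factory ``f(seed) -> fresh classifier`` for the named base."""
    if name == "svc":
        return lambda seed: CalibratedSVC(random_state=seed, **kwargs)
    if name == "logistic":
        return lambda seed: LogisticBase(random_state=seed, **kwargs)
    raise ValueError(f"unknown base classifier {name!r}; expected 'svc' or 'logistic'")
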