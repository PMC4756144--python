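"""Prediction engines.

The native engine is the nearest neighbor algorithm (NNA): a query is
assigned the class of the training sample at minimum Euclidean distance,
computed on per-feature min-max normalized values whose bounds are
learned from the training data only (raw molecular descriptors span
orders of magnitude, so unnormalized distance would be dominated by a
few columns).  Zero-range features normalize to 0 for every training
sample.  Distance ties go to the earliest training index.

Other engines (random forest, SMO-style SVM, a bagging meta-classifier
standing in for dagging) are off-the-shelf scikit-learn estimators at
their default parameters, exposed through the same fit/predict contract
so the IFS loop can drive any of them interchangeably.
"""

from __future__ import annotations

from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "Classifier",
    "NearestNeighborClassifier",
    "SklearnEngine",
    "register_engine",
    "get_engine",
    "engine_factory",
    "registered_engines",
]


@runtime_checkable
class Classifier(Protocol):
    """The contract every prediction engine honors."""

    name: str

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Classifier": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


class NotFittedError(RuntimeError):
    pass


class NearestNeighborClassifier:
    """1-nearest-neighbor on min-max normalized features (the NNA)."""

    name = "nna"

    def __init__(self) -> None:
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None
        self._min: np.ndarray | None = None
        self._scale: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestNeighborClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training set must be a non-empty 2-D matrix")
        if y.shape[0] != X.shape[0]:
            raise ValueError("label count must match training row count")
        self._min = X.min(axis=0)
        span = X.max(axis=0) - self._min
        span[span == 0] = 1.0  # zero-range features normalize to 0
        self._scale = span
        self._X = (X - self._min) / self._scale
        self._y = y.copy()
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._X is None:
            raise NotFittedError("predict called before fit")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self._X.shape[1]:
            raise ValueError(
                f"query width {X.shape[1] if X.ndim == 2 else '?'} != "
                f"training width {self._X.shape[1]}"
            )
        Q = (X - self._min) / self._scale
        d = cdist(Q, self._X, metric="euclidean")
        nearest = d.argmin(axis=1)  # argmin takes the first minimum: earliest index
        return self._y[nearest]


class SklearnEngine:
    """Adapter giving a scikit-learn estimator the engine contract."""

    def __init__(self, name: str, estimator) -> None:
        self.name = name
        self._estimator = estimator
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnEngine":
        self._estimator.fit(np.asarray(X, dtype=float), np.asarray(y))
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError("predict called before fit")
        return np.asarray(self._estimator.predict(np.asarray(X, dtype=float)))


_REGISTRY: dict[str, Callable[[int | None], Classifier]] = {}


def register_engine(name: str, factory: Callable[[int | None], Classifier]) -> None:
    """Register an engine factory under a name; factory takes a seed (or None)."""
    _REGISTRY[name] = factory


def get_engine(name: str, seed: int | None = None) -> Classifier:
    """Instantiate a registered engine, forwarding the seed if it is stochastic."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown engine {name!r}; registered engines: "
            f"{sorted(_REGISTRY)}"
        )
    return factory(seed)


def engine_factory(name: str, seed: int | None = None) -> Callable[[], Classifier]:
    """A zero-argument factory yielding fresh engine instances (one per CV fold)."""
    get_engine(name, seed)  # fail fast on unknown names
    return lambda: get_engine(name, seed)


def registered_engines() -> list[str]:
    return sorted(_REGISTRY)


register_engine("nna", lambda seed: NearestNeighborClassifier())
register_engine(
    "rf", lambda seed: SklearnEngine("rf", RandomForestClassifier(random_state=seed))
)
register_engine("smo", lambda seed: SklearnEngine("smo", SVC(random_state=seed)))
register_engine(
    "dagging",
    lambda seed: SklearnEngine("dagging", BaggingClassifier(random_state=seed)),
)
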