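"""Classifier backends: the contract and a desk-scale reference model.

Any probabilistic classifier can drive the self-training loop as long as it
honours the sklearn estimator contract: ``fit(X, y)``, ``predict_proba``
rows summing to 1, a ``classes_`` attribute, and determinism under a fixed
``random_state``.  The shipped reference backend is a multinomial logistic
(softmax) regression trained by full-batch gradient descent whose step size
follows the polynomial-decay schedule — convex and deterministic, so the
self-training mechanics can be studied without deep-training variance.

Backends register by name; experiment configs refer to them by that name.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .objective import LRScheduleConfig, polynomial_decay

__all__ = [
    "SoftmaxRegression",
    "register_backend",
    "get_backend",
    "available_backends",
    "predict_proba_in_classes",
]


class SoftmaxRegression(BaseEstimator, ClassifierMixin):
    """Multinomial logistic regression with polynomial-decay gradient descent.

    Minimizes the mean softmax cross-entropy plus an L2 penalty with
    full-batch gradient descent from a zero initialization; the step size
    at epoch ``t`` is ``init_lr * (1 - t/epochs)**power``.  Zero
    initialization and full-batch updates make training bit-reproducible:
    two fits on identical data yield identical probabilities regardless of
    ``random_state`` (the seed is accepted for contract uniformity and
    reserved for stochastic variants).

    Parameters
    ----------
    init_lr : float, default=0.5
        Base learning rate.  Chosen for standardized desk-scale features;
        the convex objective tolerates large steps.
    epochs : int, default=200
        Number of full-batch gradient steps.
    power : float, default=1.0
        Decay exponent (1 = linear decay to zero).
    l2 : float, default=1e-4
        Ridge penalty on the weights (not the intercept).
    warm_start : bool, default=False
        Continue from the previous fit's weights instead of restarting
        from zero.  The default cold restart re-derives the model from the
        augmented data alone each self-training round.
    random_state : int or None, default=None
        Accepted for the backend contract; the reference solver is
        deterministic without it.
    """

    def __init__(
        self,
        init_lr: float = 0.5,
        epochs: int = 200,
        power: float = 1.0,
        l2: float = 1e-4,
        warm_start: bool = False,
        random_state: int | None = None,
    ):
        self.init_lr = init_lr
        self.epochs = epochs
        self.power = power
        self.l2 = l2
        self.warm_start = warm_start
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.shape[0] < 2:
            raise ValueError(
                "training set contains a single class; softmax over >= 2 "
                "classes is required"
            )
        self.classes_ = classes
        n, d = X.shape
        C = classes.shape[0]
        y_idx = np.searchsorted(classes, y)
        Y = np.zeros((n, C))
        Y[np.arange(n), y_idx] = 1.0

        if self.warm_start and hasattr(self, "coef_") and self.coef_.shape == (d, C):
            W = self.coef_.copy()
            b = self.intercept_.copy()
        else:
            W = np.zeros((d, C))
            b = np.zeros(C)

        sched = LRScheduleConfig(
            init_lr=self.init_lr, total_epochs=self.epochs, power=self.power
        )
        for t in range(self.epochs):
            lr = polynomial_decay(t, sched)
            Pm = _softmax(X @ W + b)
            G = (Pm - Y) / n
            W -= lr * (X.T @ G + self.l2 * W)
            b -= lr * G.sum(axis=0)
        self.coef_ = W
        self.intercept_ = b
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.zeros((0, self.classes_.shape[0]))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return _softmax(X @ self.coef_ + self.intercept_)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


_REGISTRY: dict[str, type] = {}


def register_backend(name: str, cls: type) -> None:
    """Register an estimator class under ``name`` for config lookup."""
    _REGISTRY[name] = cls


def get_backend(name: str, **params):
    """Instantiate a registered backend by name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return cls(**params)


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


register_backend("softmax", SoftmaxRegression)


def predict_proba_in_classes(estimator, X, classes: np.ndarray) -> np.ndarray:
    """Probabilities aligned to a global class list.

    A backend fitted on a labeled subset may have seen only some of the
    global classes; unseen classes get probability zero so downstream
    selection still works over the full class set.
    """
    classes = np.asarray(classes)
    X = np.asarray(X)
    if X.shape[0] == 0:
        return np.zeros((0, classes.shape[0]))
    raw = estimator.predict_proba(X)
    est_classes = np.asarray(estimator.classes_)
    if est_classes.shape[0] == classes.shape[0] and np.all(est_classes == classes):
        return raw
    out = np.zeros((X.shape[0], classes.shape[0]))
    col = {c: j for j, c in enumerate(classes)}
    for j, c in enumerate(est_classes):
        out[:, col[c]] = raw[:, j]
    return out


def clone_backend(estimator, random_state: int | None = None):
    """Fresh unfitted copy of a backend, reseeded if it accepts a seed."""
    fresh = clone(estimator)
    if random_state is not None and "random_state" in fresh.get_params():
        fresh.set_params(random_state=random_state)
    return fresh
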