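"""Gaussian naive Bayes for binary DNA-binding prediction.

The model assumes class-conditional feature independence with Gaussian
likelihoods: P(y | x) is proportional to P(y) * prod_i N(x_i; mu_{y,i},
sigma^2_{y,i}).  Priors are class frequencies; means and variances are
per-class maximum-likelihood estimates.  Variances are floored by adding
``var_smoothing`` times the largest per-feature variance of the pooled
training data, so constant features cannot produce singular densities.
All density arithmetic is carried out in log space (the feature space has
1486 terms; a direct product underflows).

The positive class is the larger of the two training labels (1 for 0/1
labels).  A posterior of exactly 0.5 is classified positive.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import io as _io

_LOG_2PI = float(np.log(2.0 * np.pi))


def _estimate_parameters(
    X: np.ndarray, y01: np.ndarray, var_smoothing: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-class priors, means and smoothed ML variances for binary y in {0,1}."""
    n = X.shape[0]
    priors = np.array([(y01 == 0).sum() / n, (y01 == 1).sum() / n])
    theta = np.stack([X[y01 == c].mean(axis=0) for c in (0, 1)])
    var = np.stack([X[y01 == c].var(axis=0) for c in (0, 1)])  # ML (ddof=0)
    pooled_max = X.var(axis=0).max()
    epsilon = var_smoothing * (pooled_max if pooled_max > 0 else 1.0)
    return priors, var + epsilon, theta, epsilon


def _joint_log_likelihood(
    X: np.ndarray, priors: np.ndarray, theta: np.ndarray, var: np.ndarray
) -> np.ndarray:
    """n x 2 matrix of log P(y) + sum_i log N(x_i; mu_y,i, var_y,i)."""
    jll = np.empty((X.shape[0], 2))
    for c in (0, 1):
        diff = X - theta[c]
        jll[:, c] = (
            np.log(priors[c])
            - 0.5 * np.sum(_LOG_2PI + np.log(var[c]))
            - 0.5 * np.sum(diff**2 / var[c], axis=1)
        )
    return jll


def _posterior_positive(jll: np.ndarray) -> np.ndarray:
    """Normalize joint log likelihoods to the positive-class posterior."""
    m = jll.max(axis=1, keepdims=True)
    p = np.exp(jll - m)
    return p[:, 1] / p.sum(axis=1)


def gnb_fit_predict_proba(
    X_train: np.ndarray,
    y01_train: np.ndarray,
    X_test: np.ndarray,
    var_smoothing: float = 1e-9,
) -> np.ndarray:
    """Fast path used by cross-validation loops: fit on arrays, return the
    positive-class posterior for ``X_test``.  Same mathematics as
    :class:`GaussianNaiveBayes` without estimator overhead."""
    priors, var, theta, _ = _estimate_parameters(X_train, y01_train, var_smoothing)
    return _posterior_positive(_joint_log_likelihood(X_test, priors, theta, var))


class GaussianNaiveBayes(ClassifierMixin, BaseEstimator):
    """Binary Gaussian naive Bayes classifier.

    Parameters
    ----------
    var_smoothing : float, default 1e-9
        Fraction of the largest pooled per-feature variance added to every
        class-conditional variance.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is the positive class.
    class_prior_ : ndarray of shape (2,)
    theta_, var_ : ndarray of shape (2, n_features)
        Per-class means and smoothed variances.
    epsilon_ : float
        The absolute variance floor that was added.
    """

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes, y01 = np.unique(y, return_inverse=True)
        if classes.shape[0] != 2:
            raise ValueError(
                f"GaussianNaiveBayes is binary; got {classes.shape[0]} class(es): "
                f"{classes}"
            )
        counts = np.bincount(y01)
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 training samples")
        self.classes_ = classes
        priors, var, theta, eps = _estimate_parameters(X, y01, self.var_smoothing)
        self.class_prior_, self.var_, self.theta_, self.epsilon_ = priors, var, theta, eps
        self.n_features_in_ = X.shape[1]
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "theta_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fit with "
                f"{self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Posteriors, columns ordered as ``classes_``; rows sum to 1."""
        X = self._check_X(X)
        pos = _posterior_positive(
            _joint_log_likelihood(X, self.class_prior_, self.theta_, self.var_)
        )
        return np.column_stack([1.0 - pos, pos])

    def decision_function(self, X) -> np.ndarray:
        """Positive-class posterior in [0, 1] (the real-valued output used
        for ROC analysis)."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Positive iff the positive-class posterior >= 0.5 (ties positive)."""
        pos = self.decision_function(X)
        return np.where(pos >= 0.5, self.classes_[1], self.classes_[0])

    # -- serialization ------------------------------------------------------

    def to_dict(self, feature_names: list[str] | None = None) -> dict:
        check_is_fitted(self, "theta_")
        d = {
            "classes": [int(c) for c in self.classes_],
            "class_prior": self.class_prior_.tolist(),
            "theta": self.theta_.tolist(),
            "var": self.var_.tolist(),
            "epsilon": float(self.epsilon_),
            "var_smoothing": self.var_smoothing,
        }
        if feature_names is not None:
            if len(feature_names) != self.n_features_in_:
                raise ValueError("feature_names length mismatch")
            d["feature_names"] = list(feature_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianNaiveBayes":
        model = cls(var_smoothing=d.get("var_smoothing", 1e-9))
        model.classes_ = np.asarray(d["classes"])
        model.class_prior_ = np.asarray(d["class_prior"], dtype=float)
        model.theta_ = np.asarray(d["theta"], dtype=float)
        model.var_ = np.asarray(d["var"], dtype=float)
        model.epsilon_ = float(d["epsilon"])
        model.n_features_in_ = model.theta_.shape[1]
        model.feature_names_ = d.get("feature_names")
        return model

    def save(self, path, feature_names: list[str] | None = None) -> None:
        _io.write_json(self.to_dict(feature_names), path)

    @classmethod
    def load(cls, path) -> "GaussianNaiveBayes":
        return cls.from_dict(_io.read_json(path))
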