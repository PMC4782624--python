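"""Soft-margin kernel SVM on the irregularity feature, and its evaluation.

The classifier solves the standard dual problem: maximize

    Q(a) = sum_j a_j - (1/2) sum_jk a_j a_k d_j d_k K(y_j, y_k)

subject to ``sum_j d_j a_j = 0`` and ``0 <= a_j <= Gamma``, where Gamma
bounds the multipliers (soft margin) and d_j in {-1, +1} are the targets.
The decision rule is ``sign(sum_j a_j d_j K(y, y_j) + b)``. The dual is
solved by libsvm's SMO via scikit-learn; this module re-exposes the
multipliers, targets, bias and support vectors as fitted attributes and
verifies the dual constraints after every fit, so the optimization
problem being solved is explicit rather than hidden.

Class convention: abnormal = +1 = "positive" for confusion-matrix
bookkeeping; normal = -1. A decision value of exactly zero maps to +1
(abnormal), the fail-safe direction for a screening tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .entropy import FeatureVector

__all__ = [
    "HeartSoundSVC",
    "ConfusionMetrics",
    "train",
    "predict",
    "evaluate",
    "LABEL_CODES",
]

#: class-tag -> target encoding (abnormal is the positive class)
LABEL_CODES = {"abnormal": 1, "normal": -1}

_CONSTRAINT_ATOL = 1e-6


@dataclass(frozen=True)
class ConfusionMetrics:
    """TP/TN/FP/FN counts and the derived percentage scores.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total, each times 100.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sen_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def spe_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def acc_pct(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / total

    def summary(self) -> dict:
        """Counts plus scores rounded to 2 decimals, as a plain dict."""
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sen_pct": round(self.sen_pct, 2),
            "spe_pct": round(self.spe_pct, 2),
            "acc_pct": round(self.acc_pct, 2),
        }


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise distance: gamma = 1/(2 med^2)."""
    d = pdist(X)
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    med = float(np.median(d))
    return 1.0 / (2.0 * med * med)


class HeartSoundSVC(ClassifierMixin, BaseEstimator):
    """Soft-margin kernel SVM exposing its dual solution.

    Parameters
    ----------
    Gamma : float
        Box constraint on the Lagrange multipliers (the soft-margin
        trade-off); larger values penalize margin violations harder.
    kernel : {"rbf", "linear", "poly"}
        Kernel function.
    gamma : float or "median"
        RBF/poly kernel coefficient; ``"median"`` sets it from the median
        pairwise training distance (a scale-free default that copes with
        the 1-D entropy feature).
    degree, coef0 : polynomial kernel parameters.
    tol : SMO convergence tolerance.

    Fitted attributes
    -----------------
    alphas_ : multipliers a_j > 0, one per support vector.
    targets_ : d_j in {-1, +1} of the support vectors.
    support_vectors_ : the support vectors themselves.
    bias_ : intercept b.
    gamma_ : resolved kernel coefficient.
    """

    def __init__(
        self,
        Gamma: float = 1.0,
        kernel: str = "rbf",
        gamma: float | str = "median",
        degree: int = 3,
        coef0: float = 0.0,
        tol: float = 1e-6,
    ) -> None:
        self.Gamma = Gamma
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        classes = np.unique(y)
        if not np.array_equal(classes, [-1, 1]):
            raise ValueError(
                f"need both classes encoded as -1/+1, got classes {classes.tolist()}"
            )
        gamma_val = (
            _median_heuristic_gamma(X) if self.gamma == "median" else float(self.gamma)
        )
        svc = SVC(
            C=self.Gamma,
            kernel=self.kernel,
            gamma=gamma_val,
            degree=self.degree,
            coef0=self.coef0,
            tol=self.tol,
        )
        svc.fit(X, y)
        # dual_coef_[0, j] = d_j * a_j for support vector j
        dual = svc.dual_coef_[0]
        self.alphas_ = np.abs(dual)
        self.targets_ = np.sign(dual).astype(int)
        self.support_vectors_ = svc.support_vectors_
        self.bias_ = float(svc.intercept_[0])
        self.gamma_ = gamma_val
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self._svc = svc
        self._check_dual_constraints()
        return self

    def _check_dual_constraints(self) -> None:
        """Assert the dual feasibility conditions on the fitted solution."""
        balance = float(np.sum(self.alphas_ * self.targets_))
        if abs(balance) > _CONSTRAINT_ATOL * max(1.0, np.sum(self.alphas_)):
            raise RuntimeError(f"dual balance violated: sum d_j a_j = {balance:g}")
        if np.any(self.alphas_ < -_CONSTRAINT_ATOL) or np.any(
            self.alphas_ > self.Gamma + _CONSTRAINT_ATOL
        ):
            raise RuntimeError("multipliers outside [0, Gamma]")

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "alphas_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match "
                f"training dimension {self.n_features_in_}"
            )
        return self._svc.decision_function(X)

    def predict(self, X) -> np.ndarray:
        """Class in {-1, +1}; a decision value of exactly 0 maps to +1."""
        return np.where(self.decision_function(X) >= 0.0, 1, -1)


def _as_xy(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[f.sampen] for f in features], dtype=np.float64)
    y = np.array([LABEL_CODES[f.label] for f in features], dtype=int)
    return X, y


def train(
    features: list[FeatureVector],
    Gamma: float = 1.0,
    kernel: str = "rbf",
    **kernel_params,
) -> HeartSoundSVC:
    """Fit a :class:`HeartSoundSVC` on labeled irregularity features."""
    X, y = _as_xy(features)
    return HeartSoundSVC(Gamma=Gamma, kernel=kernel, **kernel_params).fit(X, y)


def predict(model: HeartSoundSVC, features) -> np.ndarray:
    """Predict -1/+1 classes for feature values or FeatureVectors."""
    if features and isinstance(features[0], FeatureVector):
        features = [[f.sampen] for f in features]
    return model.predict(np.asarray(features, dtype=np.float64))


def evaluate(predicted, true) -> ConfusionMetrics:
    """Confusion metrics with abnormal (+1) as the positive class.

    Raises
    ------
    ValueError
        On empty or length-mismatched label sequences.
    """
    predicted = np.asarray(predicted, dtype=int)
    true = np.asarray(true, dtype=int)
    if predicted.size == 0:
        raise ValueError("empty label sequences")
    if predicted.shape != true.shape:
        raise ValueError(
            f"length mismatch: {predicted.size} predictions vs {true.size} labels"
        )
    tp = int(np.sum((predicted == 1) & (true == 1)))
    tn = int(np.sum((predicted == -1) & (true == -1)))
    fp = int(np.sum((predicted == 1) & (true == -1)))
    fn = int(np.sum((predicted == -1) & (true == 1)))
    return ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn)
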