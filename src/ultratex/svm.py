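"""RBF-kernel support-vector machine training and cross-validation.

The decision function is f(x) = sgn(sum_i alpha_i d_i K(x_i, x) + b) with
the radial basis kernel K(x, x') = exp(-||x - x'||^2 / (2 sigma^2)).  The
quadratic program is delegated to scikit-learn's SVC; this module owns the
kernel-width convention (sigma^2 = half the median squared pairwise
training distance when "auto"), the stratified seeded folds, and the
accuracy bookkeeping consumed by the filter stage and the GA fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import SVMConfig
from .table import LabeledFeatureTable


def rbf_kernel(x: np.ndarray, x2: np.ndarray, kernel_width: float) -> float:
    """exp(-||x - x'||^2 / (2 sigma^2)); symmetric, in (0, 1]."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError("points must have equal dimensionality")
    if kernel_width <= 0:
        raise ValueError("kernel width must be positive")
    d2 = float(np.sum((x - x2) ** 2))
    return float(np.exp(-d2 / (2.0 * kernel_width)))


def auto_kernel_width(X: np.ndarray) -> float:
    """Median squared pairwise distance / 2 (the "auto" sigma^2 rule)."""
    X = np.asarray(X, dtype=float)
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    iu = np.triu_indices(len(X), k=1)
    med = float(np.median(np.maximum(d2[iu], 0.0)))
    return med / 2.0 if med > 0 else 1.0


@dataclass
class SVMModel:
    """A trained soft-margin RBF machine in the explicit dual form."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * d_i, one per support vector
    bias: float
    kernel_width: float
    classes: np.ndarray
    _svc: SVC = field(repr=False)

    @property
    def n_support(self) -> int:
        return len(self.support_vectors)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """sum_i alpha_i d_i K(x_i, x) + b, evaluated with the explicit kernel."""
        X = np.asarray(X, dtype=float)
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-np.maximum(d2, 0.0) / (2.0 * self.kernel_width))
        return K @ self.dual_coef + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels via the sign of the decision function."""
        sign = self.decision_values(X) >= 0
        return np.where(sign, self.classes[1], self.classes[0])


def train(X: np.ndarray, y: np.ndarray, config: SVMConfig | None = None) -> SVMModel:
    """Fit a soft-margin RBF SVM; deterministic for fixed inputs/config."""
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("training data must contain exactly two classes")
    width = auto_kernel_width(X) if config.kernel_width == "auto" else float(config.kernel_width)
    svc = SVC(C=config.C, kernel="rbf", gamma=1.0 / (2.0 * width))
    svc.fit(X, y)
    return SVMModel(
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_.ravel(),
        bias=float(svc.intercept_[0]),
        kernel_width=width,
        classes=classes,
        _svc=svc,
    )


@dataclass
class CVResult:
    """Per-fold accuracies of one stratified cross-validation run."""

    fold_accuracies: List[float]
    fold_sizes: List[int]
    fold_seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies,
            "fold_sizes": self.fold_sizes,
            "fold_seed": self.fold_seed,
            "mean_accuracy": self.mean_accuracy,
        }


def cross_validate_arrays(
    X: np.ndarray, y: np.ndarray, config: SVMConfig | None = None
) -> CVResult:
    """Stratified k-fold accuracy on raw arrays (deterministic per seed)."""
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.folds:
        raise ValueError("need >= folds samples per class")
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.fold_seed
    )
    accs, sizes = [], []
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], config)
        pred = model.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        sizes.append(len(test_idx))
    return CVResult(fold_accuracies=accs, fold_sizes=sizes, fold_seed=config.fold_seed)


def cross_validate(
    table: LabeledFeatureTable,
    features: Sequence[str],
    config: SVMConfig | None = None,
    setting_id=None,
) -> CVResult:
    """Stratified k-fold accuracy of a feature subset on one setting."""
    X, y = table.matrix(setting_id=setting_id, features=features)
    return cross_validate_arrays(X, y, config)
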