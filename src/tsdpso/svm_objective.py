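"""RBF-SVM cross-validation fitness and swarm-based hyperparameter tuning.

The classifier is a soft-margin SVM with Gaussian radial-basis kernel
``k(x, x') = exp(-gamma * ||x - x'||^2)`` (``gamma = 1/(2 sigma^2)``);
the dual quadratic program is delegated to scikit-learn's solver.  The
tuning fitness is the mean stratified k-fold misclassification rate over
``(C, gamma)``, searched in log2 space so the box is well scaled for the
swarm's speed cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .optimizer import DelayPolicy, TractionConfig, optimize_tsdpso
from .swarm import ObjectiveSpec, OptimizationResult, SwarmConfig

__all__ = [
    "SVMHyperparams",
    "SearchBounds",
    "CVSpec",
    "rbf_kernel",
    "cv_error_fitness",
    "cv_auc",
    "tune_svm_tsdpso",
]


@dataclass(frozen=True)
class SVMHyperparams:
    """Penalty factor C and kernel width gamma of the RBF-SVM."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass(frozen=True)
class SearchBounds:
    """log2-space search box for (C, gamma)."""

    log2_c: tuple[float, float] = (-5.0, 15.0)
    log2_gamma: tuple[float, float] = (-15.0, 3.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.log2_c, self.log2_gamma):
            if not lo < hi:
                raise ValueError("bounds must be increasing")


@dataclass(frozen=True)
class CVSpec:
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def rbf_kernel(x: np.ndarray, x2: np.ndarray, gamma: float) -> float:
    """Gaussian radial-basis kernel value for one pair of vectors."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError("vectors must have equal shape")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    diff = x - x2
    return float(np.exp(-gamma * np.dot(diff, diff)))


def _check_data(x: np.ndarray, y: np.ndarray, cv: CVSpec) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < cv.folds:
        raise ValueError("each class needs at least `folds` samples")
    return x, y


def _folds(y: np.ndarray, cv: CVSpec):
    skf = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)
    return skf.split(np.zeros(len(y)), y)


def cv_error_fitness(
    x: np.ndarray, y: np.ndarray, params: SVMHyperparams, cv: CVSpec
) -> float:
    """Mean held-out misclassification rate of the RBF-SVM over k folds."""
    x, y = _check_data(x, y, cv)
    errors = []
    for train, test in _folds(y, cv):
        clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
        clf.fit(x[train], y[train])
        errors.append(float(np.mean(clf.predict(x[test]) != y[test])))
    return float(np.mean(errors))


def cv_auc(
    x: np.ndarray, y: np.ndarray, params: SVMHyperparams, cv: CVSpec
) -> float:
    """Mean held-out ROC AUC over k folds (the AV-ROC diagnostic)."""
    x, y = _check_data(x, y, cv)
    aucs = []
    for train, test in _folds(y, cv):
        clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
        clf.fit(x[train], y[train])
        aucs.append(float(roc_auc_score(y[test], clf.decision_function(x[test]))))
    return float(np.mean(aucs))


def tune_svm_tsdpso(
    x: np.ndarray,
    y: np.ndarray,
    bounds: SearchBounds | None = None,
    swarm_config: SwarmConfig | None = None,
    cv: CVSpec | None = None,
    delay_policy: DelayPolicy | None = None,
    traction: TractionConfig | None = None,
    transition_x: float = 0.6,
) -> tuple[SVMHyperparams, OptimizationResult, SVC]:
    """Tune (C, gamma) with TSDPSO and refit on the full training data.

    Particles live in the 2-D (log2 C, log2 gamma) box; the fitness is
    the stratified CV error.  Returns the best hyperparameters, the
    optimization trace and the final model fit at those parameters.
    """
    bounds = bounds or SearchBounds()
    swarm_config = swarm_config or SwarmConfig()
    cv = cv or CVSpec()
    x, y = _check_data(x, y, cv)

    def fitness(z: np.ndarray) -> float:
        params = SVMHyperparams(C=2.0 ** z[0], gamma=2.0 ** z[1])
        return cv_error_fitness(x, y, params, cv)

    objective = ObjectiveSpec(
        dimension=2,
        lower=np.array([bounds.log2_c[0], bounds.log2_gamma[0]]),
        upper=np.array([bounds.log2_c[1], bounds.log2_gamma[1]]),
        evaluate=fitness,
        name="svm_cv_error",
    )
    result = optimize_tsdpso(
        objective,
        swarm_config,
        delay_policy=delay_policy,
        traction=traction,
        transition_x=transition_x,
    )
    best = SVMHyperparams(
        C=2.0 ** result.gbest_position[0], gamma=2.0 ** result.gbest_position[1]
    )
    model = SVC(C=best.C, gamma=best.gamma, kernel="rbf")
    model.fit(x, y)
    return best, result, model
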