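"""Classifier specifications and hyperparameter selection protocols.

Four classifier variants are compared on the voxel-intensity features:
a linear SVM, an RBF-kernel SVM, an SVM on PCA-reduced features, and a
random forest.  The learning machinery is delegated to scikit-learn; this
module pins the experimental protocol around it — the RBF (C, γ) grid
search with repeated random 10-subject holdouts, the PCA retained-variance
sweep from 70% to 99%, and the random-forest defaults of t = 60 trees with
√D features per split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "linear_svm",
    "rbf_svm",
    "pca_svm",
    "random_forest",
    "make_estimator",
    "train",
    "rbf_grid_search",
    "pca_fraction_sweep",
    "rf_defaults",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)


@dataclass(frozen=True)
class ClassifierSpec:
    variant: str  # linear_svm | rbf_svm | pca_svm | random_forest
    C: float = 1.0
    gamma: float = 0.1
    variance_fraction: float = 0.95
    n_trees: int = 60
    max_features: int | str | None = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("linear_svm", "rbf_svm", "pca_svm", "random_forest"):
            raise ValueError(f"unknown classifier variant {self.variant!r}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if not (0 < self.variance_fraction < 1):
            raise ValueError("variance_fraction must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")


def linear_svm(C: float = 1.0) -> ClassifierSpec:
    return ClassifierSpec("linear_svm", C=C)


def rbf_svm(C: float = 1.0, gamma: float = 0.1) -> ClassifierSpec:
    return ClassifierSpec("rbf_svm", C=C, gamma=gamma)


def pca_svm(variance_fraction: float = 0.95, C: float = 1.0) -> ClassifierSpec:
    return ClassifierSpec("pca_svm", variance_fraction=variance_fraction, C=C)


def random_forest(n_trees: int = 60, max_features: int | str | None = "sqrt", seed: int = 0) -> ClassifierSpec:
    return ClassifierSpec("random_forest", n_trees=n_trees, max_features=max_features, seed=seed)


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator matching a spec."""
    if spec.variant == "linear_svm":
        return SVC(kernel="linear", C=spec.C)
    if spec.variant == "rbf_svm":
        return SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
    if spec.variant == "pca_svm":
        return Pipeline(
            [
                ("pca", PCA(n_components=spec.variance_fraction, svd_solver="full", random_state=spec.seed)),
                ("svm", SVC(kernel="linear", C=spec.C)),
            ]
        )
    return RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.max_features,
        random_state=spec.seed,
    )


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    """Fit the specified classifier; deterministic for a fixed spec seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 training rows")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    model = make_estimator(spec)
    model.fit(X, y)
    return model


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Real-valued confidence for the positive (second) class of the model."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    # random forest: fraction of trees voting for the positive class
    proba = model.predict_proba(X)
    return np.asarray(proba[:, -1], dtype=float)


def rbf_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    holdout_n: int = 10,
    repeats: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (C, γ) search by repeated random holdout validation.

    Each repeat holds out ``holdout_n`` randomly chosen subjects, trains on
    the remainder, and scores every grid point on the holdout.  The point
    with the highest mean holdout accuracy wins; exact ties go to the
    smaller C, then the smaller γ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("hyperparameter grids must be nonempty")
    n = X.shape[0]
    if holdout_n >= n:
        raise ValueError("holdout size must be smaller than the cohort")
    rng = np.random.default_rng(seed)
    grid = [(C, g) for C in C_grid for g in gamma_grid]
    acc = np.zeros(len(grid))
    done = 0
    for _ in range(repeats):
        test_idx = rng.choice(n, size=holdout_n, replace=False)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if np.unique(y[train_mask]).size < 2:
            continue
        for gi, (C, g) in enumerate(grid):
            model = SVC(kernel="rbf", C=C, gamma=g)
            model.fit(X[train_mask], y[train_mask])
            acc[gi] += np.mean(model.predict(X[test_idx]) == y[test_idx])
        done += 1
    if done == 0:
        raise ValueError("no valid holdout split found")
    acc /= done
    # lexicographic tie-break: accuracy desc, then C asc, then gamma asc
    order = sorted(range(len(grid)), key=lambda i: (-acc[i], grid[i][0], grid[i][1]))
    return grid[order[0]]


def pca_fraction_sweep(
    X: np.ndarray,
    y: np.ndarray,
    fractions: Sequence[float] | None = None,
    cv: int = 10,
    seed: int = 0,
    default: float = 0.95,
) -> float:
    """Sweep retained-variance fractions 0.70…0.99 and pick the CV-best one.

    Returns ``default`` (0.95) when the accuracy profile is flat, i.e. no
    fraction beats the accuracy at the default by more than one held-out
    sample's worth.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 1:
        raise ValueError("feature matrix has rank 0 after centering")
    fractions = list(fractions) if fractions is not None else [round(0.70 + 0.01 * i, 2) for i in range(30)]
    k = min(cv, int(np.min(np.bincount(np.unique(y, return_inverse=True)[1]))))
    k = max(k, 2)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = {}
    for frac in fractions:
        model = make_estimator(pca_svm(variance_fraction=frac))
        scores[frac] = float(np.mean(cross_val_score(model, X, y, cv=splitter)))
    best = max(scores, key=lambda f: (scores[f], -f))
    margin = 1.0 / X.shape[0]
    if default in scores and scores[best] - scores[default] <= margin:
        return default
    return best


def rf_defaults(D: int) -> tuple[int, int]:
    """Default forest size and per-split feature count for width-D features.

    t = 60 trees; f = floor(√D) randomly sampled candidate features per
    node, the standard classification default.  Both can be overridden on
    the :class:`ClassifierSpec`.
    """
    if D < 1:
        raise ValueError("feature width must be at least 1")
    return 60, max(1, int(np.floor(np.sqrt(D))))
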