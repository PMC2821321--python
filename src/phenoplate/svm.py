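"""Multi-class soft-margin SVM with an RBF kernel, in one-vs-one form.

Training delegates the quadratic program to libsvm (through scikit-learn's
``SVC``) and then extracts the complete solution — support vectors, dual
coefficients, intercepts — into the persistable :class:`~phenoplate.data.Model`
container. Prediction, pairwise decision values and the boundary-proximity
score are computed here directly from that container, so a reloaded model
reproduces the decision function exactly, with no hidden state.

Features are linearly rescaled to [-1, 1] per feature from the training
min/max (the libsvm convention); prediction applies the stored scaling
internally. Per-class penalties multiply C, letting minority phenotypes be
up-weighted. Cross-validation is stratified 5-fold by default, seeded and
deterministic; the C/gamma grid search follows the standard libsvm-guide
powers-of-two grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .data import Model

__all__ = [
    "ScalingParams",
    "CVResult",
    "GridSearchResult",
    "fit_scaling",
    "apply_scaling",
    "train_model",
    "predict",
    "decision_values",
    "boundary_score",
    "cross_validate",
    "grid_search",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

DEFAULT_C_GRID = [2.0**e for e in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**e for e in range(-15, 4, 2)]


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature (min, max) measured on the training data."""

    bounds: dict[str, tuple[float, float]]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if hi < lo:
                raise ValueError(f"scaling min > max for feature {name!r}")


def fit_scaling(X: np.ndarray, feature_names: list[str] | None = None) -> ScalingParams:
    """Per-feature min/max of the training matrix. Missing values are a hard
    error here: scaling feeds training, where silent imputation would bias
    the classifier."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    bad = np.nonzero(~np.isfinite(X).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"missing/non-finite feature values in rows {bad.tolist()[:20]}")
    bounds = {
        name: (float(X[:, j].min()), float(X[:, j].max()))
        for j, name in enumerate(feature_names)
    }
    return ScalingParams(bounds, tuple(feature_names))


def apply_scaling(
    X: np.ndarray, scaling: ScalingParams, feature_names: list[str] | None = None
) -> np.ndarray:
    """Map each feature linearly so the training min -> -1 and max -> +1.

    Values outside the training range extrapolate linearly (no clipping);
    constant features map to 0.
    """
    X = np.asarray(X, dtype=float)
    names = list(feature_names) if feature_names is not None else list(scaling.feature_names)
    unknown = [n for n in names if n not in scaling.bounds]
    if unknown:
        raise KeyError(f"features not covered by scaling: {unknown}")
    out = np.empty_like(X, dtype=float)
    for j, name in enumerate(names):
        lo, hi = scaling.bounds[name]
        if hi == lo:
            out[:, j] = 0.0
        else:
            out[:, j] = 2.0 * (X[:, j] - lo) / (hi - lo) - 1.0
    return out


def _as_scaling(model: Model) -> ScalingParams:
    return ScalingParams(
        {k: tuple(v) for k, v in model.scaling.items()},
        tuple(model.feature_names),
    )


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    gamma: float = 1.0,
    class_weights: dict[str, float] | None = None,
    feature_names: list[str] | None = None,
    class_names: list[str] | None = None,
) -> Model:
    """Train a one-vs-one RBF SVM and capture its full state.

    ``class_weights`` multiply the penalty C for the given classes (default
    1). ``class_names`` may declare the expected classes; a declared class
    with no training sample is an error. Scaling is fit on X and stored in
    the model.
    """
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object).astype(str)
    present = sorted(str(c) for c in set(y))
    if class_names is None:
        class_names = present
    else:
        empty = [c for c in class_names if c not in present]
        if empty:
            raise ValueError(f"declared classes with zero training samples: {empty}")
        undeclared = [c for c in present if c not in class_names]
        if undeclared:
            raise ValueError(f"training labels outside declared classes: {undeclared}")
        class_names = sorted(str(c) for c in class_names)
    if len(class_names) < 2:
        raise ValueError("training needs at least 2 classes")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    weights = dict(class_weights or {})
    for c, w in weights.items():
        if w <= 0:
            raise ValueError(f"class weight for {c!r} must be positive")

    scaling = fit_scaling(X, feature_names)
    Xs = apply_scaling(X, scaling)
    svc = SVC(
        C=C,
        gamma=gamma,
        kernel="rbf",
        class_weight={c: weights.get(c, 1.0) for c in class_names},
        decision_function_shape="ovo",
    )
    svc.fit(Xs, y)
    # sklearn sorts classes lexicographically, matching class_names above
    assert list(svc.classes_) == class_names
    dual_coef = np.asarray(svc.dual_coef_, dtype=float)
    intercepts = np.atleast_1d(np.asarray(svc.intercept_, dtype=float))
    if len(class_names) == 2:
        # sklearn stores the binary solution sign-flipped (its decision value
        # favors classes_[1]); flip back to the uniform one-vs-one convention
        # where positive favors the first class of the pair.
        dual_coef = -dual_coef
        intercepts = -intercepts
    return Model(
        class_names=class_names,
        feature_names=list(feature_names),
        scaling=dict(scaling.bounds),
        support_vectors=np.asarray(svc.support_vectors_, dtype=float),
        n_support=[int(n) for n in svc.n_support_],
        dual_coef=dual_coef,
        intercepts=intercepts,
        C=float(C),
        gamma=float(gamma),
        class_weights={c: float(weights.get(c, 1.0)) for c in class_names},
    )


def _check_features(model: Model, feature_names: list[str] | None) -> list[str]:
    if feature_names is None:
        return list(model.feature_names)
    if set(feature_names) != set(model.feature_names):
        raise KeyError(
            f"feature mismatch: model expects {model.feature_names}, got {feature_names}"
        )
    return list(feature_names)


def _scaled(model: Model, X: np.ndarray, feature_names: list[str] | None) -> np.ndarray:
    names = _check_features(model, feature_names)
    X = np.asarray(X, dtype=float)
    # reorder columns to the model's canonical feature order
    idx = [names.index(n) for n in model.feature_names]
    return apply_scaling(X[:, idx], _as_scaling(model))


def _pairwise_decisions(model: Model, Xs: np.ndarray) -> np.ndarray:
    """All k(k-1)/2 one-vs-one decision values, libsvm formulation.

    For pair (i, j), positive favors class i (the first class of the pair in
    ``model.class_pairs`` order).
    """
    sv = model.support_vectors
    d2 = (
        (Xs**2).sum(axis=1)[:, None]
        + (sv**2).sum(axis=1)[None, :]
        - 2.0 * Xs @ sv.T
    )
    K = np.exp(-model.gamma * np.clip(d2, 0.0, None))
    starts = np.concatenate([[0], np.cumsum(model.n_support)])
    k = model.n_classes
    dec = np.empty((Xs.shape[0], model.n_pairs))
    for p, (i, j) in enumerate(itertools.combinations(range(k), 2)):
        si = slice(starts[i], starts[i + 1])
        sj = slice(starts[j], starts[j + 1])
        dec[:, p] = (
            K[:, si] @ model.dual_coef[j - 1, si]
            + K[:, sj] @ model.dual_coef[i, sj]
            + model.intercepts[p]
        )
    return dec


def decision_values(
    model: Model, X: np.ndarray, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Signed pairwise decision values, one column per class pair.

    Columns are labelled ``"a|b"``; positive favors class ``a``.
    """
    dec = _pairwise_decisions(model, _scaled(model, X, feature_names))
    cols = [f"{a}|{b}" for a, b in model.class_pairs]
    return pd.DataFrame(dec, columns=cols)


def _vote(model: Model, dec: np.ndarray) -> np.ndarray:
    """Majority vote over pairwise decisions; ties broken by the largest sum
    of winning pairwise |decision values|, then by class order."""
    n, k = dec.shape[0], model.n_classes
    votes = np.zeros((n, k), dtype=int)
    strength = np.zeros((n, k))
    for p, (i, j) in enumerate(itertools.combinations(range(k), 2)):
        wins_i = dec[:, p] > 0
        votes[wins_i, i] += 1
        votes[~wins_i, j] += 1
        strength[wins_i, i] += np.abs(dec[wins_i, p])
        strength[~wins_i, j] += np.abs(dec[~wins_i, p])
    out = np.empty(n, dtype=object)
    for r in range(n):
        top = votes[r].max()
        cand = np.nonzero(votes[r] == top)[0]
        if cand.size > 1:
            best = strength[r, cand].max()
            cand = cand[strength[r, cand] == best]
        out[r] = model.class_names[cand[0]]
    return out.astype(str)


def predict(
    model: Model, X: np.ndarray, feature_names: list[str] | None = None
) -> np.ndarray:
    """Predicted class per row (scaling applied internally)."""
    dec = _pairwise_decisions(model, _scaled(model, X, feature_names))
    return _vote(model, dec)


def boundary_score(
    model: Model, X: np.ndarray, feature_names: list[str] | None = None
) -> np.ndarray:
    """Proximity of each object to a decision boundary (lower = closer).

    The score is the minimum |decision value| over the pairwise functions
    that involve the object's predicted class; it is 0 exactly on a pairwise
    decision surface of the predicted class.
    """
    dec = _pairwise_decisions(model, _scaled(model, X, feature_names))
    labels = _vote(model, dec)
    pairs = list(itertools.combinations(range(model.n_classes), 2))
    name_idx = {c: i for i, c in enumerate(model.class_names)}
    scores = np.empty(len(labels))
    for r, lab in enumerate(labels):
        ci = name_idx[lab]
        vals = [abs(dec[r, p]) for p, (i, j) in enumerate(pairs) if ci in (i, j)]
        scores[r] = min(vals)
    return scores


@dataclass
class CVResult:
    """k-fold cross-validation outcome.

    ``accuracy`` is the fraction of held-out objects predicted correctly,
    pooled over all folds (= trace/total of the confusion matrix); the
    confusion matrix has trained classes as rows and predicted as columns.
    """

    accuracy: float
    confusion: pd.DataFrame
    fold_seed: int


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    C: float = 1.0,
    gamma: float = 1.0,
    class_weights: dict[str, float] | None = None,
    seed: int = 0,
    stratified: bool = True,
    feature_names: list[str] | None = None,
) -> CVResult:
    """Seeded k-fold cross-validation with per-fold scaling.

    For each fold, scaling and the model are fit on the other k-1 folds and
    the held-out fold is predicted; the confusion matrix aggregates every
    held-out prediction. Folds are stratified by default so small classes
    appear in every fold (set ``stratified=False`` for a plain random split).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object).astype(str)
    classes = sorted(set(y))
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValueError(f"classes with fewer than k={k} members: {small}")
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for train_idx, test_idx in splitter.split(X, y):
        m = train_model(
            X[train_idx], y[train_idx], C=C, gamma=gamma,
            class_weights=class_weights, feature_names=feature_names,
        )
        pred = predict(m, X[test_idx], feature_names=feature_names)
        for t, p in zip(y[test_idx], pred):
            conf.loc[t, p] += 1
    total = conf.to_numpy().sum()
    accuracy = float(np.trace(conf.to_numpy()) / total)
    return CVResult(accuracy=accuracy, confusion=conf, fold_seed=seed)


@dataclass
class GridSearchResult:
    """C/gamma grid-search outcome: every grid point's CV accuracy plus the
    selected pair (highest accuracy; ties -> smallest C, then smallest gamma)."""

    grid: list[tuple[float, float, float]]  # (C, gamma, cv_accuracy)
    best: tuple[float, float]

    @property
    def best_accuracy(self) -> float:
        return max(a for _, _, a in self.grid)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: list[float] | None = None,
    gamma_grid: list[float] | None = None,
    k: int = 5,
    class_weights: dict[str, float] | None = None,
    seed: int = 0,
    stratified: bool = True,
) -> GridSearchResult:
    """Cross-validate every (C, gamma) of the grid with the same fold seed."""
    C_grid = list(C_grid) if C_grid is not None else DEFAULT_C_GRID
    gamma_grid = list(gamma_grid) if gamma_grid is not None else DEFAULT_GAMMA_GRID
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    grid = []
    for C in C_grid:
        for gamma in gamma_grid:
            res = cross_validate(
                X, y, k=k, C=C, gamma=gamma, class_weights=class_weights,
                seed=seed, stratified=stratified,
            )
            grid.append((float(C), float(gamma), res.accuracy))
    best = min(
        grid, key=lambda t: (-t[2], t[0], t[1])
    )  # max accuracy, ties -> smallest C then gamma
    return GridSearchResult(grid=grid, best=(best[0], best[1]))
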