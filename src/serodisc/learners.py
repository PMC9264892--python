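"""Classifier families behind one uniform contract, plus SMOTE and CV tuning.

Three families are supported, mirroring common chemometric practice for
serum spectral diagnostics:

* ``plsda``  — PLS regression on the 0/1 class indicator (PLS1/NIPALS via
  sklearn), score = predicted response, label threshold 0.5;
* ``rf``     — 500-tree random forest with Gini splits, score = fraction of
  trees voting the positive class, Gini importances retained;
* ``svm_linear`` — soft-margin linear SVM, score = decision function.

Scores are always oriented so that larger means more cancer-like.  SMOTE is
implemented from first principles (k-nearest-neighbour convex interpolation
within the minority class); hyperparameters are tuned by patient-grouped
5-fold cross-validation with ties broken toward the simpler model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .errors import DegenerateDataError

FAMILIES = ("rf", "plsda", "svm_linear")

DEFAULT_N_TREES = 500
DEFAULT_SMOTE_K = 5
DEFAULT_SVM_COSTS = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_PLS_COMPONENTS = tuple(range(1, 16))


def default_rf_mtry(n_features: int) -> tuple:
    """mtry grid {round(sqrt(p)), p/4, p/2}, deduplicated, ascending."""
    cand = {max(1, int(round(np.sqrt(n_features)))),
            max(1, n_features // 4), max(1, n_features // 2)}
    return tuple(sorted(cand))


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameter grid and tuned choice.

    The grid is a dict with a single entry (``n_latent``, ``mtry`` or
    ``cost``); ``tuned`` holds the chosen value after :func:`tune_cv`.
    ``None`` grids are filled with family defaults at tune time.
    """

    family: str
    grid: Optional[dict] = None
    tuned: Optional[dict] = None
    n_trees: int = DEFAULT_N_TREES

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.grid is not None and not any(self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def resolved_grid(self, n_features: int) -> dict:
        if self.grid is not None:
            return {k: sorted(v) for k, v in self.grid.items()}
        if self.family == "plsda":
            return {"n_latent": list(DEFAULT_PLS_COMPONENTS)}
        if self.family == "rf":
            return {"mtry": list(default_rf_mtry(n_features))}
        return {"cost": list(DEFAULT_SVM_COSTS)}


class FittedModel:
    """Uniform wrapper: ``score(X)`` continuous (larger = more cancer-like),
    ``predict(X)`` 0/1 labels, deterministic given the fitted state."""

    def __init__(self, family, estimator, score_fn, threshold, importances=None):
        self.family = family
        self.estimator = estimator
        self._score_fn = score_fn
        self.threshold = threshold
        self.feature_importances_ = importances

    def score(self, X) -> np.ndarray:
        return np.asarray(self._score_fn(np.asarray(X, dtype=float))).ravel()

    def predict(self, X) -> np.ndarray:
        return (self.score(X) >= self.threshold).astype(int)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if np.unique(y).size < 2:
        raise DegenerateDataError("both classes must be present in y")
    return X, y


def fit_plsda(X, y, n_latent: int) -> FittedModel:
    """PLS-DA: PLS1 on the 0/1 indicator; successive score vectors are
    mutually orthogonal (NIPALS deflation).  Label threshold 0.5."""
    X, y = _check_xy(X, y)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_latent <= limit:
        raise ValueError(f"n_latent={n_latent} outside [1, {limit}]")
    est = PLSRegression(n_components=n_latent, scale=False)
    est.fit(X, y.astype(float))
    return FittedModel("plsda", est, lambda Z: est.predict(Z).ravel(), 0.5)


def fit_rf(X, y, mtry: int, n_trees: int = DEFAULT_N_TREES, seed: int = 0,
           bootstrap: bool = True) -> FittedModel:
    """Random forest of Gini-split CARTs; per-feature mean decrease in Gini
    exposed as ``feature_importances_``; score = positive-class vote
    fraction (trees are grown to purity, so tree probabilities are votes)."""
    X, y = _check_xy(X, y)
    if mtry > X.shape[1]:
        raise ValueError(f"mtry={mtry} exceeds {X.shape[1]} features")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        criterion="gini",
        bootstrap=bootstrap,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    est.fit(X, y)
    pos = int(np.flatnonzero(est.classes_ == 1)[0])
    return FittedModel(
        "rf", est, lambda Z: est.predict_proba(Z)[:, pos], 0.5,
        importances=est.feature_importances_,
    )


def fit_svm_linear(X, y, cost: float) -> FittedModel:
    """Soft-margin linear SVM; score = signed margin, positive toward
    cancer (class 1)."""
    if cost <= 0:
        raise ValueError("cost must be positive")
    X, y = _check_xy(X, y)
    est = SVC(kernel="linear", C=cost)
    est.fit(X, y)
    # sklearn orients decision_function toward classes_[1]; with 0/1 labels
    # classes_[1] == 1 == cancer, so no flip is needed.
    return FittedModel("svm_linear", est, est.decision_function, 0.0)


def fit_model(spec: ModelSpec, X, y, seed: int = 0) -> FittedModel:
    """Dispatch on family using ``spec.tuned`` hyperparameters."""
    if spec.tuned is None:
        raise ValueError("ModelSpec has no tuned hyperparameters; run tune_cv")
    if spec.family == "plsda":
        n = min(spec.tuned["n_latent"], np.asarray(X).shape[0] - 1,
                np.asarray(X).shape[1])
        return fit_plsda(X, y, n)
    if spec.family == "rf":
        return fit_rf(X, y, spec.tuned["mtry"], spec.n_trees, seed)
    return fit_svm_linear(X, y, spec.tuned["cost"])


def smote(X, y, k: int = DEFAULT_SMOTE_K, target: Optional[dict] = None,
          seed: int = 0):
    """Synthetic minority oversampling.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0,1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbours of ``x_i``
    (Euclidean).  Originals are preserved unchanged; synthetic rows are
    appended until per-class counts reach ``target`` (default: balance all
    classes up to the majority count).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if target is None:
        target = {int(c): int(counts.max()) for c in classes}
    rng = np.random.default_rng(int(seed) % (2**31))
    new_X, new_y = [X], [y]
    for c in classes:
        idx = np.flatnonzero(y == c)
        need = int(target.get(int(c), idx.size)) - idx.size
        if need <= 0:
            continue
        if idx.size <= k:
            raise DegenerateDataError(
                f"class {c} has {idx.size} samples, need > k={k} for SMOTE"
            )
        members = X[idx]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
        neigh = nn.kneighbors(members, return_distance=False)[:, 1:]
        base = rng.integers(0, idx.size, size=need)
        pick = neigh[base, rng.integers(0, k, size=need)]
        u = rng.uniform(0.0, 1.0, size=(need, 1))
        new_X.append(members[base] + u * (members[pick] - members[base]))
        new_y.append(np.full(need, c, dtype=int))
    if len(new_X) == 1:
        return X.copy(), y.copy()
    return np.vstack(new_X), np.concatenate(new_y)


def tune_cv(X, y, spec: ModelSpec, folds: int = 5, seed: int = 0,
            groups=None, sampling: str = "none",
            smote_k: int = DEFAULT_SMOTE_K) -> ModelSpec:
    """Choose the grid value maximizing mean CV accuracy.

    Folds are grouped by patient when ``groups`` is given (no replicate
    leakage into validation folds) and stratified by class.  SMOTE, when
    requested, is applied inside each fold's training part only.  Ties
    break toward the simpler model: the grid is scanned in ascending order
    (fewer latent variables / smaller mtry / smaller cost) and the first
    maximum wins.
    """
    X, y = _check_xy(X, y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = spec.resolved_grid(X.shape[1])
    (param, values), = grid.items()
    if len(values) == 1:
        return replace(spec, tuned={param: values[0]})

    if groups is not None:
        groups = np.asarray(groups)
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                        random_state=int(seed) % (2**31))
        split_iter = list(splitter.split(X, y, groups))
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=int(seed) % (2**31))
        split_iter = list(splitter.split(X, y))

    means = []
    for value in values:
        accs = []
        for f, (tr, va) in enumerate(split_iter):
            Xtr, ytr = X[tr], y[tr]
            if sampling == "smote":
                Xtr, ytr = smote(Xtr, ytr, k=smote_k, seed=seed * 1000 + f)
            try:
                model = fit_model(replace(spec, tuned={param: value}),
                                  Xtr, ytr, seed=seed * 1000 + f)
            except ValueError:
                accs.append(-np.inf)  # infeasible candidate for this fold
                continue
            accs.append(float(np.mean(model.predict(X[va]) == y[va])))
        means.append(float(np.mean(accs)))
    best = int(np.argmax(means))  # first max -> simplest on ties
    return replace(spec, tuned={param: values[best]})
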