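"""RBF-SVM with metaheuristic (c, g) tuning, grid search and a PLS-DA baseline.

The SVM kernel is K(u, v) = exp(-g * ||u - v||^2); the penalty c and kernel
width g are searched inside the box [2^-2, 2^8]^2.  The tuning fitness is
the stratified 5-fold cross-validated accuracy of the training set, with the
fold assignment held fixed across all fitness evaluations of one tuning run
so optimizer comparisons are paired.

Reflectance bands already share one physical scale, so features are fed to
the kernel unscaled by default: per-band standardization inflates squared
distances to roughly twice the band count, which saturates
exp(-g*||u-v||^2) everywhere inside the printed g box once more than a few
dozen bands are kept.  Set ``standardize=True`` in svm_train/cv_fitness
for features that genuinely live on different scales (the scaler is then
fit per CV fold to avoid leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .optimize import OptimizerResult, RsaParams, SearchSpace, minimize

PARAM_BOUNDS = (2.0**-2, 2.0**8)


@dataclass
class SvmParams:
    """Penalty c and RBF width g, both constrained to [2^-2, 2^8]."""

    c: float
    g: float

    def __post_init__(self) -> None:
        lo, hi = PARAM_BOUNDS
        if not (lo <= self.c <= hi and lo <= self.g <= hi):
            raise ValueError(
                f"(c, g) = ({self.c}, {self.g}) outside the search box "
                f"[{lo}, {hi}]^2"
            )


@dataclass
class TrainedClassifier:
    """A fitted model plus the bookkeeping needed to reuse it."""

    family: str
    model: object
    classes: np.ndarray
    feature_indices: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.feature_indices is not None and X.shape[1] != self.feature_indices.size:
            X = X[:, self.feature_indices]
        if self.family == "plsda":
            scores = self.model.predict(X)
            return self.classes[np.argmax(scores, axis=1)]
        return self.model.predict(X)


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    return y


def svm_train(
    X, y, params: SvmParams, standardize: bool = False,
    feature_indices: np.ndarray | None = None,
) -> TrainedClassifier:
    """Multiclass RBF-SVM (one-vs-one with majority voting)."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    steps = [StandardScaler()] if standardize else []
    steps.append(SVC(C=params.c, gamma=params.g, kernel="rbf",
                     decision_function_shape="ovo"))
    model = make_pipeline(*steps)
    model.fit(X, y)
    return TrainedClassifier(
        family="svm",
        model=model,
        classes=np.unique(y),
        feature_indices=feature_indices,
        extra={"params": params},
    )


def cv_fitness(
    X, y, params: SvmParams, folds: int = 5, seed: int | None = None,
    standardize: bool = False,
) -> float:
    """Stratified k-fold CV accuracy of an RBF-SVM at (c, g)."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < folds]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than {folds} members; "
            "cannot stratify"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        steps = [StandardScaler()] if standardize else []
        steps.append(SVC(C=params.c, gamma=params.g, kernel="rbf"))
        model = make_pipeline(*steps).fit(X[tr], y[tr])
        correct += int(np.sum(model.predict(X[te]) == y[te]))
    return correct / X.shape[0]


def tune_svm(
    X, y, optimizer: str = "mrsa", params: RsaParams | None = None,
    folds: int = 5, bounds: tuple[float, float] = PARAM_BOUNDS,
) -> tuple[SvmParams, OptimizerResult]:
    """Search the (c, g) box maximizing CV accuracy with a chosen optimizer.

    Internally minimizes 1 - accuracy; the returned trace is converted back
    to the accuracy scale (non-decreasing).
    """
    params = params if params is not None else RsaParams()
    # fold assignment shared across every fitness evaluation of this run
    fold_seed = (
        int(np.random.default_rng(params.seed).integers(2**31))
        if params.seed is not None else 0
    )

    def objective(pos):
        return 1.0 - cv_fitness(
            X, y, SvmParams(c=float(pos[0]), g=float(pos[1])),
            folds=folds, seed=fold_seed,
        )

    space = SearchSpace(lower=[bounds[0], bounds[0]], upper=[bounds[1], bounds[1]])
    if callable(optimizer):
        result = optimizer(objective, space, params)
    else:
        result = minimize(optimizer, objective, space, params)
    accuracy_trace = 1.0 - result.trace
    tuned = SvmParams(c=float(result.best_position[0]), g=float(result.best_position[1]))
    return tuned, OptimizerResult(
        best_position=result.best_position,
        best_fitness=1.0 - result.best_fitness,
        trace=accuracy_trace,
        evaluations=result.evaluations,
    )


def grid_search_cg(
    X, y, c_grid, g_grid, folds: int = 5, seed: int | None = None
) -> SvmParams:
    """Exhaustive (c, g) grid search; ties go to smaller c, then smaller g."""
    c_grid = sorted(float(c) for c in c_grid)
    g_grid = sorted(float(g) for g in g_grid)
    if not c_grid or not g_grid:
        raise ValueError("grids must be non-empty")
    best_params, best_fit = None, -np.inf
    for c in c_grid:
        for g in g_grid:
            fit = cv_fitness(X, y, SvmParams(c=c, g=g), folds=folds, seed=seed)
            if fit > best_fit + 1e-12:
                best_fit, best_params = fit, SvmParams(c=c, g=g)
    return best_params


def plsda_train(
    X, y, max_lv: int = 15, folds: int = 5, seed: int | None = None
) -> TrainedClassifier:
    """PLS-DA: one-hot PLS regression, latent-variable count picked by CV."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)

    rank_cap = int(min(X.shape[1], X.shape[0] - np.ceil(X.shape[0] / folds) - 1))
    if max_lv > rank_cap:
        warnings.warn(
            f"max_lv={max_lv} exceeds what the data support; capping at {rank_cap}",
            UserWarning,
        )
    cap = max(1, min(max_lv, rank_cap))

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_lv, best_acc = 1, -np.inf
    for lv in range(1, cap + 1):
        correct = 0
        for tr, te in splits:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls = PLSRegression(n_components=lv, scale=True).fit(X[tr], Y[tr])
            pred = classes[np.argmax(pls.predict(X[te]), axis=1)]
            correct += int(np.sum(pred == y[te]))
        acc = correct / X.shape[0]
        if acc > best_acc + 1e-12:
            best_acc, best_lv = acc, lv

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = PLSRegression(n_components=best_lv, scale=True).fit(X, Y)
    return TrainedClassifier(
        family="plsda",
        model=final,
        classes=classes,
        extra={"n_components": best_lv, "cv_accuracy": best_acc},
    )


# -- sklearn estimator facade ----------------------------------------------

class OptimizedSVC(ClassifierMixin, BaseEstimator):
    """RBF-SVM whose (c, g) are tuned by a metaheuristic during ``fit``.

    Parameters
    ----------
    optimizer : 'mrsa' | 'rsa' | 'ga' | 'pso'
    n_candidates, max_iters : population size and iteration budget.
    folds : CV folds of the tuning fitness.
    bounds : (low, high) for both c and g.
    random_state : master seed for initialization and fold assignment.

    Fitted attributes: ``c_``, ``g_``, ``cv_fitness_``, ``trace_`` (accuracy
    per iteration), ``classes_``, ``estimator_`` (the refit pipeline).
    """

    def __init__(self, optimizer: str = "mrsa", n_candidates: int = 20,
                 max_iters: int = 50, folds: int = 5,
                 bounds: tuple[float, float] = PARAM_BOUNDS,
                 random_state: int | None = None):
        self.optimizer = optimizer
        self.n_candidates = n_candidates
        self.max_iters = max_iters
        self.folds = folds
        self.bounds = bounds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _check_labels(y)
        rsa_params = RsaParams(
            n_candidates=self.n_candidates, max_iters=self.max_iters,
            seed=self.random_state,
        )
        tuned, result = tune_svm(
            X, y, optimizer=self.optimizer, params=rsa_params,
            folds=self.folds, bounds=self.bounds,
        )
        self.c_, self.g_ = tuned.c, tuned.g
        self.cv_fitness_ = result.best_fitness
        self.trace_ = result.trace
        self.classes_ = np.unique(y)
        self.estimator_ = svm_train(X, y, tuned).model
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(np.asarray(X, dtype=float))


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA with CV-selected latent-variable count (sklearn facade)."""

    def __init__(self, max_lv: int = 15, folds: int = 5,
                 random_state: int | None = None):
        self.max_lv = max_lv
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        trained = plsda_train(X, y, max_lv=self.max_lv, folds=self.folds,
                              seed=self.random_state)
        self.model_ = trained
        self.classes_ = trained.classes
        self.n_components_ = trained.extra["n_components"]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)
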