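"""Wavelength selection: CARS and SPA.

CARS (competitive adaptive reweighted sampling) runs a Monte-Carlo loop: each
run fits a PLS model on a random calibration subset of the currently retained
bands, ranks bands by absolute regression coefficient, shrinks the retained
count along an exponentially decreasing schedule (EDF), resamples bands with
coefficient-proportional weights (ARS), and scores the surviving subset by
cross-validated misclassification.  The subset with the lowest CV error wins.

SPA (successive projections algorithm) grows, from every candidate start
band, a chain of minimally collinear bands via orthogonal projections, and
scores each chain prefix in a cardinality window by cross-validated accuracy
of the downstream classifier.

Classification is fed to the PLS machinery as one-hot class indicators and
decoded by argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class SelectionResult:
    """Selected band indices (0-based, sorted) plus run diagnostics."""

    selected_indices: np.ndarray
    selected_wavelengths: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("selection must keep at least one band")
        if len(set(idx.tolist())) != idx.size:
            raise ValueError("selected indices must be unique")
        self.selected_indices = np.sort(idx)


def edf_schedule(p: int, runs: int) -> np.ndarray:
    """Retention ratios r_i = a*exp(-k*i), i = 1..runs.

    The boundary conditions r_1 * p = p and r_runs * p = 2 give
    a = (p/2)^(1/(runs-1)) and k = ln(p/2)/(runs-1).
    """
    if runs < 2:
        raise ValueError("runs must be >= 2")
    a = (p / 2.0) ** (1.0 / (runs - 1))
    k = np.log(p / 2.0) / (runs - 1)
    i = np.arange(1, runs + 1)
    return a * np.exp(-k * i)


def _one_hot(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _pls_coefficients(X, Y, n_components):
    pls = PLSRegression(n_components=n_components, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, Y)
    return pls


def _pls_cv_error(X, y, Y, classes, n_components, folds, seed):
    """Stratified CV misclassification rate of argmax-decoded PLS."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = 0
    for tr, te in skf.split(X, y):
        ncomp = int(min(n_components, X.shape[1], len(tr) - 1))
        pls = _pls_coefficients(X[tr], Y[tr], max(1, ncomp))
        pred = np.argmax(pls.predict(X[te]), axis=1)
        truth = np.argmax(Y[te], axis=1)
        errors += int(np.sum(pred != truth))
    return errors / X.shape[0]


def _choose_components(X, y, Y, classes, cap, folds, seed):
    cap = int(min(cap, X.shape[1], X.shape[0] - np.ceil(X.shape[0] / folds) - 1))
    cap = max(1, cap)
    best_nc, best_err = 1, np.inf
    for nc in range(1, cap + 1):
        err = _pls_cv_error(X, y, Y, classes, nc, folds, seed)
        if err < best_err - 1e-12:
            best_err, best_nc = err, nc
    return best_nc


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 50,
    folds: int = 5,
    seed: int | None = None,
    calibration_fraction: float = 0.8,
    max_components: int = 10,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling on a classification matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 bands")
    if runs < 2:
        raise ValueError("runs must be >= 2")
    if np.unique(y).size < 2:
        raise ValueError("CARS needs at least 2 classes")

    rng = np.random.default_rng(seed)
    Y, classes = _one_hot(y)
    ratios = edf_schedule(p, runs)
    score_seed = int(rng.integers(2**31)) if seed is not None else None

    retained = np.arange(p)
    subsets, sizes, cv_errors = [], [], []
    for i in range(runs):
        n_keep = min(max(2, int(np.floor(ratios[i] * p + 0.5))), retained.size)
        cal = rng.choice(n, size=max(2, int(round(calibration_fraction * n))), replace=False)
        ncomp = _choose_components(
            X[np.ix_(cal, retained)], y[cal], Y[cal], classes,
            max_components, folds, score_seed,
        )
        pls = _pls_coefficients(X[np.ix_(cal, retained)], Y[cal], ncomp)
        weights = np.linalg.norm(np.atleast_2d(pls.coef_), axis=0)
        if not np.any(weights > 0):
            warnings.warn("all PLS coefficients are zero; using uniform ARS weights",
                          UserWarning)
            weights = np.ones(retained.size)
        # EDF forced selection: keep the n_keep strongest bands
        order = np.argsort(weights)[::-1]
        pool = order[:n_keep]
        # ARS: weighted sampling with replacement within the pool
        probs = weights[pool] / weights[pool].sum()
        drawn = rng.choice(pool, size=n_keep, replace=True, p=probs)
        retained = np.sort(retained[np.unique(drawn)])

        err = _pls_cv_error(
            X[:, retained], y, Y, classes,
            min(max_components, retained.size), folds, score_seed,
        )
        subsets.append(retained.copy())
        sizes.append(retained.size)
        cv_errors.append(err)

    cv_errors = np.asarray(cv_errors)
    best = min(range(runs), key=lambda i: (cv_errors[i], sizes[i], i))
    return SelectionResult(
        selected_indices=subsets[best],
        diagnostics={
            "subset_sizes": np.asarray(sizes),
            "cv_errors": cv_errors,
            "best_run": best,
            "edf_ratios": ratios,
        },
    )


def spa_chain(X: np.ndarray, start: int, n_select: int) -> np.ndarray:
    """Successive-projection chain of band indices beginning at ``start``.

    Each step adds the band whose component orthogonal to the span of the
    already-selected bands has maximal norm.  Raises if the design runs out
    of independent columns before the chain is complete.
    """
    R = np.array(X, dtype=float)
    p = R.shape[1]
    chain = [start]
    for _ in range(n_select - 1):
        v = R[:, chain[-1]].copy()
        nv = v @ v
        if nv < 1e-12:
            raise ValueError("rank-deficient design: fewer independent bands than requested")
        R -= np.outer(v, (v @ R) / nv)
        norms = np.einsum("ij,ij->j", R, R)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < 1e-12:
            raise ValueError("rank-deficient design: fewer independent bands than requested")
        chain.append(nxt)
    return np.asarray(chain, dtype=int)


def _default_spa_scorer(folds: int, seed: int | None):
    def score(X, y):
        clf = make_pipeline(StandardScaler(), SVC(C=1.0, gamma="scale"))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        correct = 0
        for tr, te in skf.split(X, y):
            clf.fit(X[tr], y[tr])
            correct += int(np.sum(clf.predict(X[te]) == y[te]))
        return correct / X.shape[0]

    return score


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    n_min: int = 5,
    n_max: int = 20,
    folds: int = 5,
    seed: int | None = None,
    scorer=None,
) -> SelectionResult:
    """Successive projections algorithm over a cardinality window."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if n_min < 1 or n_max < n_min:
        raise ValueError("need 1 <= n_min <= n_max")
    if n_max > p:
        raise ValueError("n_max cannot exceed the number of bands")

    # autoscale so projections compare information, not raw magnitude
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd

    score = scorer if scorer is not None else _default_spa_scorer(folds, seed)

    best = None  # (accuracy, -cardinality as tie-break via ordering below)
    per_cardinality: dict[int, float] = {}
    chain_errors = 0
    for start in range(p):
        try:
            chain = spa_chain(Xs, start, n_max)
        except ValueError:
            chain_errors += 1
            continue
        for m in range(n_min, n_max + 1):
            acc = score(X[:, chain[:m]], y)
            per_cardinality[m] = max(per_cardinality.get(m, 0.0), acc)
            key = (acc, -m, -start)
            if best is None or key > best[0]:
                best = (key, chain[:m].copy())
    if best is None:
        raise ValueError("rank-deficient design: no SPA chain of the requested length exists")
    return SelectionResult(
        selected_indices=best[1],
        diagnostics={
            "per_cardinality_accuracy": per_cardinality,
            "best_accuracy": best[0][0],
            "failed_starts": chain_errors,
        },
    )


class _BandSelectorMixin:
    def transform(self, X):
        return np.asarray(X)[:, self.selected_indices_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def get_support(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_indices_] = True
        return mask


class CARSSelector(_BandSelectorMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`cars_select`."""

    def __init__(self, runs: int = 50, folds: int = 5, max_components: int = 10,
                 random_state: int | None = None):
        self.runs = runs
        self.folds = folds
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        result = cars_select(
            X, y, runs=self.runs, folds=self.folds,
            seed=self.random_state, max_components=self.max_components,
        )
        self.n_features_in_ = X.shape[1]
        self.selected_indices_ = result.selected_indices
        self.result_ = result
        return self


class SPASelector(_BandSelectorMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`spa_select`."""

    def __init__(self, n_min: int = 5, n_max: int = 20, folds: int = 5,
                 random_state: int | None = None):
        self.n_min = n_min
        self.n_max = n_max
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        result = spa_select(
            X, y, n_min=self.n_min, n_max=self.n_max,
            folds=self.folds, seed=self.random_state,
        )
        self.n_features_in_ = X.shape[1]
        self.selected_indices_ = result.selected_indices
        self.result_ = result
        return self
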