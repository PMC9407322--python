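"""Multiclass oversampling for imbalanced spectra: ROS, SMOTE, BL-SMOTE, ADASYN.

Each minority class is oversampled independently against the union of the
other classes until every class matches the majority-class count.  All
interpolation partners come from the same class (borderline-1 convention),
so synthetic points always lie on a segment between two real points of
their class.  The number of nearest neighbors k (and the borderline danger
test size m) defaults to 5 everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .dataset import SpectraSet

logger = logging.getLogger(__name__)

METHODS = ("none", "ros", "smote", "blsmote", "adasyn")


@dataclass
class OversampleConfig:
    method: str = "blsmote"
    k_neighbors: int = 5
    m_neighbors: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _class_partition(y: np.ndarray) -> tuple[dict, object]:
    """Class -> index map and the majority class label."""
    classes, counts = np.unique(y, return_counts=True)
    index = {c: np.flatnonzero(y == c) for c in classes}
    majority = classes[np.argmax(counts)]
    return index, majority


def _same_class_neighbors(Xc: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """k nearest same-class neighbor indices per row (self excluded)."""
    n = Xc.shape[0]
    k_eff = min(k, n - 1)
    if k_eff < k:
        warnings.warn(
            f"class has only {n} samples; using {k_eff} same-class neighbors "
            f"instead of {k}",
            UserWarning,
        )
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
    _, idx = nn.kneighbors(Xc)
    return idx[:, 1:], k_eff


def _interpolate(
    Xc: np.ndarray,
    seeds: np.ndarray,
    neighbors: np.ndarray,
    n_new: int,
    rng: np.random.Generator,
    quotas: np.ndarray | None = None,
) -> np.ndarray:
    """SMOTE-style linear interpolation between seed rows and their neighbors.

    ``seeds`` are row indices into ``Xc`` eligible as interpolation origins;
    ``neighbors`` holds same-class neighbor indices per row of Xc.  If
    ``quotas`` is given it specifies how many points each seed generates,
    otherwise seeds are drawn uniformly.
    """
    if quotas is None:
        origin = rng.choice(seeds, size=n_new, replace=True)
    else:
        origin = np.repeat(seeds, quotas)
    out = np.empty((len(origin), Xc.shape[1]))
    for row, i in enumerate(origin):
        j = neighbors[i][rng.integers(neighbors.shape[1])]
        lam = rng.random()
        out[row] = Xc[i] + lam * (Xc[j] - Xc[i])
    return out


class RandomOverSampler(BaseEstimator):
    """Balance classes by replicating existing minority rows at random."""

    def __init__(self, random_state: int | None = None):
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        index, majority = _class_partition(y)
        target = index[majority].size
        new_X, new_y = [X], [y]
        for c, idx in index.items():
            if idx.size == 0:
                raise ValueError(f"class {c!r} is empty")
            deficit = target - idx.size
            if deficit > 0:
                picks = rng.choice(idx, size=deficit, replace=True)
                new_X.append(X[picks])
                new_y.append(np.full(deficit, c, dtype=y.dtype))
        return np.vstack(new_X), np.concatenate(new_y)


class SMOTE(BaseEstimator):
    """Synthetic minority oversampling by same-class k-NN interpolation."""

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def _synthesize(self, X, y, c, idx, n_new, rng):
        Xc = X[idx]
        neighbors, _ = _same_class_neighbors(Xc, self.k_neighbors)
        return _interpolate(Xc, np.arange(Xc.shape[0]), neighbors, n_new, rng)

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        index, majority = _class_partition(y)
        target = index[majority].size
        new_X, new_y = [X], [y]
        for c, idx in index.items():
            deficit = target - idx.size
            if deficit <= 0:
                continue
            if idx.size < 2:
                raise ValueError(
                    f"class {c!r} has {idx.size} sample(s); SMOTE needs at least 2"
                )
            synth = self._synthesize(X, y, c, idx, deficit, rng)
            new_X.append(synth)
            new_y.append(np.full(deficit, c, dtype=y.dtype))
        return np.vstack(new_X), np.concatenate(new_y)


def classify_minority_samples(
    X: np.ndarray, y: np.ndarray, minority_class, m_neighbors: int = 5
) -> dict[str, np.ndarray]:
    """Borderline categorisation of minority samples into noise/danger/safe.

    For each minority sample, among its m nearest neighbors over ALL classes
    (self excluded) let m' be the count from other classes: m' = m is noise,
    m/2 <= m' < m is danger, anything less is safe.  Returns index arrays
    (into the minority rows) per category.
    """
    idx = np.flatnonzero(y == minority_class)
    m_eff = min(m_neighbors, X.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=m_eff + 1).fit(X)
    _, all_nbrs = nn.kneighbors(X[idx])
    other = (y[all_nbrs[:, 1:]] != minority_class).sum(axis=1)
    noise = np.flatnonzero(other == m_eff)
    danger = np.flatnonzero((other >= m_eff / 2) & (other < m_eff))
    safe = np.flatnonzero(other < m_eff / 2)
    return {"noise": noise, "danger": danger, "safe": safe}


class BorderlineSMOTE(SMOTE):
    """Borderline-1 SMOTE: interpolate only from boundary ("danger") seeds.

    Falls back to plain SMOTE (with a logged warning) for a minority class
    with no danger samples, so the balance contract always holds.
    """

    def __init__(
        self,
        k_neighbors: int = 5,
        m_neighbors: int = 5,
        random_state: int | None = None,
    ):
        super().__init__(k_neighbors=k_neighbors, random_state=random_state)
        self.m_neighbors = m_neighbors

    def _synthesize(self, X, y, c, idx, n_new, rng):
        cats = classify_minority_samples(X, y, c, self.m_neighbors)
        danger = cats["danger"]
        if danger.size == 0:
            warnings.warn(
                f"class {c!r} has no danger samples; falling back to plain SMOTE",
                UserWarning,
            )
            logger.warning("borderline-SMOTE fallback to SMOTE for class %r", c)
            return super()._synthesize(X, y, c, idx, n_new, rng)
        Xc = X[idx]
        neighbors, _ = _same_class_neighbors(Xc, self.k_neighbors)
        return _interpolate(Xc, danger, neighbors, n_new, rng)


class ADASYN(SMOTE):
    """Adaptive synthetic sampling: quota per seed follows local difficulty.

    Difficulty r_i is the fraction of other-class members among the k
    all-class neighbors of minority sample i; quotas are round(r_i_hat * G)
    and the result is trimmed/padded to exact balance.
    """

    def _synthesize(self, X, y, c, idx, n_new, rng):
        Xc = X[idx]
        k_eff = min(self.k_neighbors, X.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
        _, all_nbrs = nn.kneighbors(Xc)
        r = (y[all_nbrs[:, 1:]] != c).sum(axis=1) / k_eff
        if r.sum() == 0:
            warnings.warn(
                f"class {c!r} shows no learning difficulty anywhere; "
                "using uniform quotas",
                UserWarning,
            )
            r_hat = np.full(idx.size, 1.0 / idx.size)
        else:
            r_hat = r / r.sum()
        quotas = np.floor(r_hat * n_new + 0.5).astype(int)
        neighbors, _ = _same_class_neighbors(Xc, self.k_neighbors)
        synth = _interpolate(
            Xc, np.arange(Xc.shape[0]), neighbors, 0, rng, quotas=quotas
        )
        # rounding slack: trim at random or pad with extra difficulty-weighted draws
        if synth.shape[0] > n_new:
            keep = rng.choice(synth.shape[0], size=n_new, replace=False)
            synth = synth[np.sort(keep)]
        elif synth.shape[0] < n_new:
            extra_seeds = rng.choice(idx.size, size=n_new - synth.shape[0], p=r_hat)
            extra = _interpolate(
                Xc, np.arange(Xc.shape[0]), neighbors, 0, rng,
                quotas=np.bincount(extra_seeds, minlength=idx.size),
            )
            synth = np.vstack([synth, extra])
        return synth


_SAMPLERS = {
    "ros": RandomOverSampler,
    "smote": SMOTE,
    "blsmote": BorderlineSMOTE,
    "adasyn": ADASYN,
}


def _make_sampler(cfg: OversampleConfig):
    if cfg.method == "ros":
        return RandomOverSampler(random_state=cfg.seed)
    if cfg.method == "smote":
        return SMOTE(k_neighbors=cfg.k_neighbors, random_state=cfg.seed)
    if cfg.method == "blsmote":
        return BorderlineSMOTE(
            k_neighbors=cfg.k_neighbors,
            m_neighbors=cfg.m_neighbors,
            random_state=cfg.seed,
        )
    if cfg.method == "adasyn":
        return ADASYN(k_neighbors=cfg.k_neighbors, random_state=cfg.seed)
    raise ValueError(f"no sampler for method {cfg.method!r}")


def oversample(train: SpectraSet, cfg: OversampleConfig) -> SpectraSet:
    """Apply the configured oversampler to a SpectraSet (training data only)."""
    if cfg.method == "none":
        return train
    sampler = _make_sampler(cfg)
    X_res, y_res = sampler.fit_resample(train.reflectance, train.labels)
    n_orig = train.n_samples
    n_new = X_res.shape[0] - n_orig
    tag = cfg.method.upper()
    new_ids = np.concatenate(
        [train.ids, np.array([f"{tag}-{i:04d}" for i in range(n_new)], dtype=object)]
    )
    return SpectraSet(
        wavelengths=train.wavelengths.copy(),
        reflectance=X_res,
        labels=y_res,
        ids=new_ids,
    )


def random_oversample(train: SpectraSet, cfg: OversampleConfig) -> SpectraSet:
    return oversample(train, OversampleConfig("ros", cfg.k_neighbors, cfg.m_neighbors, cfg.seed))


def smote(train: SpectraSet, cfg: OversampleConfig) -> SpectraSet:
    return oversample(train, OversampleConfig("smote", cfg.k_neighbors, cfg.m_neighbors, cfg.seed))


def borderline_smote(train: SpectraSet, cfg: OversampleConfig) -> SpectraSet:
    return oversample(train, OversampleConfig("blsmote", cfg.k_neighbors, cfg.m_neighbors, cfg.seed))


def adasyn(train: SpectraSet, cfg: OversampleConfig) -> SpectraSet:
    return oversample(train, OversampleConfig("adasyn", cfg.k_neighbors, cfg.m_neighbors, cfg.seed))
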