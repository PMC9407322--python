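"""Labelled Vis-NIR spectra container, synthetic generator and stratified split.

The three fruit classes are NM (normal), SH (starch-head) and MD (mildewed).
Starch-head fruit sit spectrally between normal and mildewed fruit; mildewed
fruit reflect the least light and show the widest sample-to-sample spread.
The generator emulates diffuse-reflectance curves over 400-1100 nm: low
reflectance in the pigment-absorbing visible region, a sharp "red edge" rise
around 600-750 nm, and absorption valleys near 890 nm (C-H third overtone)
and 990 nm (O-H second overtone, moisture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

CLASSES: tuple[str, str, str] = ("NM", "SH", "MD")
LABEL_TO_INT = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class SpectraSet:
    """A labelled reflectance matrix with an explicit wavelength axis.

    Parameters
    ----------
    wavelengths : (B,) strictly increasing array, nm.
    reflectance : (n, B) array, dimensionless reflectance in (0, 1.2).
    labels : (n,) array of class strings from ``CLASSES``.
    ids : (n,) array of unique sample identifiers.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    labels: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be a 2-D samples x bands matrix")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"reflectance has {self.reflectance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.reflectance.shape[0] != self.labels.size or self.labels.size != self.ids.size:
            raise ValueError("reflectance rows, labels and ids must have equal length")
        unknown = set(self.labels) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if len(set(self.ids)) != self.ids.size:
            raise ValueError("sample ids must be unique")

    # -- convenience views ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.reflectance

    @property
    def y(self) -> np.ndarray:
        """Integer-encoded labels (NM=0, SH=1, MD=2)."""
        return np.array([LABEL_TO_INT[l] for l in self.labels], dtype=int)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASSES}

    def subset(self, index: np.ndarray) -> "SpectraSet":
        index = np.asarray(index)
        if index.dtype == object or not index.size:
            index = index.astype(int)
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[index],
            labels=self.labels[index],
            ids=self.ids[index],
        )

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path) -> None:
        cols = [f"R{w:.2f}" for w in self.wavelengths]
        df = pd.DataFrame(self.reflectance, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c.startswith("R")]
        wavelengths = np.array([float(c[1:]) for c in band_cols])
        return cls(
            wavelengths=wavelengths,
            reflectance=df[band_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=object),
            ids=df["id"].astype(str).to_numpy(dtype=object),
        )


@dataclass
class SimConfig:
    """Settings for the synthetic spectra generator.

    ``class_counts`` defaults to the study's 200 normal / 302 starch-head /
    98 mildewed samples.  ``scatter_mult`` and ``scatter_add`` are the
    half-widths of the per-sample multiplicative and additive scatter
    coefficients (what multiplicative scatter correction removes);
    ``noise_sd`` is the per-class band noise standard deviation, largest for
    the mildewed class.
    """

    class_counts: tuple[int, int, int] = (200, 302, 98)
    n_bands: int = 934
    band_range: tuple[float, float] = (400.0, 1100.0)
    scatter_mult: float = 0.15
    scatter_add: float = 0.02
    noise_sd: tuple[float, float, float] = (0.010, 0.018, 0.055)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.class_counts) != 3 or any(c < 0 for c in self.class_counts):
            raise ValueError("class_counts must be three non-negative integers")
        if sum(self.class_counts) == 0:
            raise ValueError("cannot generate an empty SpectraSet (zero total samples)")
        if self.n_bands < 4:
            raise ValueError("n_bands must be at least 4")
        low, high = self.band_range
        if not low < high:
            raise ValueError("band_range low must be below high")
        if self.noise_sd[2] < self.noise_sd[0]:
            raise ValueError("mildewed-class noise_sd must be >= normal-class noise_sd")


# Rise amplitudes give the NM > SH > MD ordering of mean reflectance above
# the red edge; valleys are carved proportionally so they stay visible.
_CLASS_AMPLITUDE = {"NM": 0.62, "SH": 0.50, "MD": 0.38}
_BASELINE = 0.08


def class_base_curve(wavelengths: np.ndarray, label: str) -> np.ndarray:
    """Noise-free mean reflectance curve for one class."""
    wl = np.asarray(wavelengths, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-(wl - 680.0) / 30.0))
    dip_ch = 0.10 * np.exp(-(((wl - 890.0) / 22.0) ** 2))
    dip_oh = 0.16 * np.exp(-(((wl - 990.0) / 28.0) ** 2))
    template = rise * (1.0 - dip_ch - dip_oh)
    return _BASELINE + _CLASS_AMPLITUDE[label] * template


def generate_spectra(config: SimConfig) -> SpectraSet:
    """Draw a synthetic 3-class Vis-NIR reflectance data set.

    Each sample is ``(1 + a_i) * base_class + b_i + noise`` with per-sample
    scatter coefficients ``a_i ~ U(+-scatter_mult)``, ``b_i ~ U(+-scatter_add)``
    and band noise that mixes a smooth correlated component with white noise.
    """
    rng = np.random.default_rng(config.seed)
    wl = np.linspace(config.band_range[0], config.band_range[1], config.n_bands)

    rows, labels, ids = [], [], []
    counter = 0
    for label, count, noise_sd in zip(CLASSES, config.class_counts, config.noise_sd):
        base = class_base_curve(wl, label)
        for _ in range(count):
            a = rng.uniform(-config.scatter_mult, config.scatter_mult)
            b = rng.uniform(-config.scatter_add, config.scatter_add)
            smooth = gaussian_filter1d(rng.standard_normal(config.n_bands), sigma=8.0)
            sd = smooth.std()
            smooth = smooth / sd if sd > 0 else smooth
            noise = noise_sd * (0.6 * smooth + 0.4 * rng.standard_normal(config.n_bands))
            spectrum = (1.0 + a) * base + b + noise
            rows.append(np.clip(spectrum, 1e-4, 1.199))
            labels.append(label)
            ids.append(f"{label}-{counter:04d}")
            counter += 1

    return SpectraSet(
        wavelengths=wl,
        reflectance=np.vstack(rows),
        labels=np.array(labels, dtype=object),
        ids=np.array(ids, dtype=object),
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    data: SpectraSet, train_fraction: float, seed: int | None = None
) -> tuple[SpectraSet, SpectraSet]:
    """Per-class shuffled split with round-half-up training counts.

    Per-class training size is round(count * fraction); any residual against
    the rounded overall total is absorbed by the largest class so the grand
    totals match (e.g. 200/302/98 at 0.7 gives 140/211/69 train and
    60/91/29 test).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    counts = data.class_counts()
    present = [c for c in CLASSES if counts[c] > 0]
    n_train_per_class = {c: _round_half_up(counts[c] * train_fraction) for c in present}
    target_total = _round_half_up(data.n_samples * train_fraction)
    residual = target_total - sum(n_train_per_class.values())
    if residual != 0:
        largest = max(present, key=lambda c: counts[c])
        n_train_per_class[largest] = int(
            np.clip(n_train_per_class[largest] + residual, 0, counts[largest])
        )

    train_idx, test_idx = [], []
    for c in present:
        idx = np.flatnonzero(data.labels == c)
        if counts[c] == 1:
            warnings.warn(
                f"class {c} has a single sample; assigning it to the training set",
                UserWarning,
            )
            train_idx.extend(idx.tolist())
            continue
        rng.shuffle(idx)
        n_train = n_train_per_class[c]
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())

    return data.subset(np.sort(train_idx)), data.subset(np.sort(test_idx))
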