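"""Band cropping and multiplicative scatter correction (MSC).

MSC regresses each spectrum on a reference spectrum (the training-set mean)
and inverts the fitted additive offset and multiplicative slope, removing
scatter effects that vary sample to sample.  The reference is fit on the
training set only and reused for the test set so no test information leaks
into preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectraSet

SLOPE_TOL = 1e-8


@dataclass
class MscReference:
    """Mean training spectrum used as the MSC regression target."""

    reference_spectrum: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reference_spectrum = np.asarray(self.reference_spectrum, dtype=float)
        if not np.all(np.isfinite(self.reference_spectrum)):
            raise ValueError("MSC reference must be finite")


def crop_wavelengths(data: SpectraSet, low: float, high: float) -> SpectraSet:
    """Keep bands with ``low <= wavelength <= high``, order preserved."""
    if not low < high:
        raise ValueError("low must be below high")
    mask = (data.wavelengths >= low) & (data.wavelengths <= high)
    if not mask.any():
        raise ValueError(
            f"no bands fall inside the requested range [{low}, {high}] nm "
            f"(axis spans {data.wavelengths[0]:.1f}-{data.wavelengths[-1]:.1f} nm)"
        )
    return SpectraSet(
        wavelengths=data.wavelengths[mask],
        reflectance=data.reflectance[:, mask],
        labels=data.labels.copy(),
        ids=data.ids.copy(),
    )


class MSCCorrector(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction as an sklearn transformer.

    ``fit`` stores the column-mean reference; ``transform`` regresses each
    row ``x`` on the reference (``x = a + b*ref``) and returns
    ``(x - a) / b``.  Rows whose fitted slope magnitude falls below
    ``slope_tol`` (essentially flat spectra) are passed through unchanged
    with a warning.
    """

    def __init__(self, slope_tol: float = SLOPE_TOL):
        self.slope_tol = slope_tol

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("MSC needs at least 2 training spectra for a meaningful reference")
        self.reference_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.reference_.size:
            raise ValueError("band axis of X does not match the fitted reference")
        ref = self.reference_
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        x_mean = X.mean(axis=1)
        slope = (X - x_mean[:, None]) @ ref_c / denom
        intercept = x_mean - slope * ref.mean()
        flat = np.abs(slope) < self.slope_tol
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} spectra have near-zero MSC slope; passing them "
                "through uncorrected",
                UserWarning,
            )
        safe_slope = np.where(flat, 1.0, slope)
        corrected = (X - np.where(flat, 0.0, intercept)[:, None]) / safe_slope[:, None]
        return corrected


def msc_fit(train: SpectraSet) -> MscReference:
    """Column-mean reference spectrum from the training set."""
    corrector = MSCCorrector().fit(train.reflectance)
    return MscReference(
        reference_spectrum=corrector.reference_, wavelengths=train.wavelengths.copy()
    )


def msc_apply(data: SpectraSet, ref: MscReference) -> SpectraSet:
    """Apply MSC against a previously fitted reference."""
    if ref.reference_spectrum.size != data.n_bands:
        raise ValueError("MSC reference length does not match the band axis")
    corrector = MSCCorrector()
    corrector.reference_ = ref.reference_spectrum
    corrector.n_features_in_ = ref.reference_spectrum.size
    corrected = corrector.transform(data.reflectance)
    return SpectraSet(
        wavelengths=data.wavelengths.copy(),
        reflectance=corrected,
        labels=data.labels.copy(),
        ids=data.ids.copy(),
    )
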