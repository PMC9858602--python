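"""Spectral pretreatments: SNV, MSC and Savitzky-Golay smoothing.

Each pretreatment is a scikit-learn transformer operating on a plain
``(n_samples, n_wavelengths)`` array; the module-level functions wrap them
for :class:`~meatspec.containers.SpectraSet` inputs. All calibration-derived
statistics (the MSC reference spectrum) are learned in ``fit`` and reused in
``transform``, so prediction-set spectra are corrected against the
calibration reference and never against their own mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import SpectraSet
from .exceptions import ConfigError, DegenerateSpectrumError, ScatterFitError

PRETREATMENT_METHODS = ("raw", "snv", "msc", "sg")


@dataclass
class PretreatmentSpec:
    """Declarative description of one pretreatment.

    ``sg_window``/``sg_order`` only apply to ``method="sg"``; with
    ``method="raw"`` everything else is ignored.
    """

    method: str = "raw"
    sg_window: int = 11
    sg_order: int = 2

    def __post_init__(self) -> None:
        if self.method not in PRETREATMENT_METHODS:
            raise ConfigError(
                f"unknown pretreatment '{self.method}' (expected {PRETREATMENT_METHODS})"
            )
        if self.method == "sg":
            if self.sg_window % 2 == 0:
                raise ConfigError("sg_window must be odd")
            if self.sg_window <= self.sg_order:
                raise ConfigError("sg_window must exceed sg_order")


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: standardize each spectrum (row) in place.

    Each row x becomes ``(x - mean(x)) / sd(x)`` with the n-1 (sample)
    standard deviation. Stateless; ``fit`` only validates.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=2)
        sd = X.std(axis=1, ddof=1)
        if np.any(sd == 0):
            row = int(np.flatnonzero(sd == 0)[0])
            raise DegenerateSpectrumError(
                f"constant spectrum at row {row}: SNV undefined"
            )
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed on the reference r by ordinary least squares,
    ``x ~ a + b r``, and corrected to ``(x - a) / b``. The reference is the
    calibration-set mean spectrum unless one is supplied.

    Parameters
    ----------
    reference : array of shape (n_wavelengths,), optional
        Fixed reference; default is the column mean of the data seen in fit.
    min_slope : float
        Fitted |b| below this raises :class:`ScatterFitError`.
    """

    def __init__(self, reference=None, min_slope: float = 1e-8):
        self.reference = reference
        self.min_slope = min_slope

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        self.n_features_in_ = X.shape[1]
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float).ravel()
            if ref.size != X.shape[1]:
                raise ValueError(
                    f"reference length {ref.size} != wavelength count {X.shape[1]}"
                )
        else:
            ref = X.mean(axis=0)
        if np.ptp(ref) == 0:
            raise DegenerateSpectrumError("MSC reference spectrum is constant")
        self.reference_ = ref
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=2)
        r = self.reference_
        rc = r - r.mean()
        denom = rc @ rc
        b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
        a = X.mean(axis=1) - b * r.mean()
        small = np.abs(b) < self.min_slope
        if small.any():
            row = int(np.flatnonzero(small)[0])
            raise ScatterFitError(
                f"MSC slope |b|={abs(b[row]):.2e} below tolerance at row {row}"
            )
        return (X - a[:, None]) / b[:, None]


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Savitzky-Golay least-squares polynomial smoothing along wavelengths.

    Interior points are convolved with the standard S-G kernel; the first
    and last half-windows are filled by evaluating the polynomial fitted to
    the edge window, so the grid never shrinks.
    """

    def __init__(self, window: int = 11, polyorder: int = 2):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ConfigError("window must be odd and greater than polyorder")
        if self.window > X.shape[1]:
            raise ValueError(
                f"window {self.window} exceeds wavelength count {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=2)
        if self.window > X.shape[1]:
            raise ValueError(
                f"window {self.window} exceeds wavelength count {X.shape[1]}"
            )
        return savgol_filter(X, self.window, self.polyorder, axis=1, mode="interp")


class Identity(TransformerMixin, BaseEstimator):
    """No-op pretreatment (the 'raw' arm of method comparisons)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return check_array(X)


def make_transformer(spec: PretreatmentSpec):
    """Instantiate the (unfitted) transformer a PretreatmentSpec describes."""
    if spec.method == "raw":
        return Identity()
    if spec.method == "snv":
        return SNV()
    if spec.method == "msc":
        return MSC()
    return SavitzkyGolay(window=spec.sg_window, polyorder=spec.sg_order)


# ---------------------------------------------------------------------------
# SpectraSet-level wrappers


def snv(spectra: SpectraSet) -> SpectraSet:
    """Apply SNV row standardization to every spectrum."""
    try:
        out = SNV().fit_transform(spectra.reflectance)
    except DegenerateSpectrumError as err:
        row = int(str(err).split("row ")[1].split(":")[0])
        raise DegenerateSpectrumError(
            f"constant spectrum for sample '{spectra.sample_ids[row]}': SNV undefined"
        ) from None
    return spectra.with_reflectance(out)


def msc(
    spectra: SpectraSet, reference: np.ndarray | None = None
) -> tuple[SpectraSet, np.ndarray]:
    """Apply MSC; returns the corrected spectra and the reference used."""
    est = MSC(reference=reference).fit(spectra.reflectance)
    return spectra.with_reflectance(est.transform(spectra.reflectance)), est.reference_


def sg_smooth(spectra: SpectraSet, spec: PretreatmentSpec | None = None) -> SpectraSet:
    """Savitzky-Golay smooth every spectrum; grid and wavelengths unchanged."""
    spec = spec or PretreatmentSpec(method="sg")
    est = SavitzkyGolay(window=spec.sg_window, polyorder=spec.sg_order)
    return spectra.with_reflectance(est.fit_transform(spectra.reflectance))
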