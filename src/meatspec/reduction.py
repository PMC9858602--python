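"""The four spectral dimension-reduction methods under comparison.

* correlation-threshold band extraction (keep wavelengths whose reflectance
  correlates with the target above a cutoff),
* bidirectional stepwise regression (partial-F entry/removal),
* sampling-interval shortening (keep every k-th wavelength, emulating a
  lower-resolution instrument),
* jump features from peak-to-trough (JFPT: reflectance differences between
  each peak and its adjacent troughs along the mean spectrum).

Each method is exposed both as a scikit-learn estimator on plain arrays and
as a function on :class:`~meatspec.containers.SpectraSet`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import find_peaks, peak_prominences
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .containers import QualityTable, SpectraSet
from .exceptions import EmptySelectionError, NoStructureError
from .preprocessing import PretreatmentSpec, SavitzkyGolay

logger = logging.getLogger(__name__)

REDUCTION_METHODS = ("correlation", "stepwise", "decimation", "jfpt")


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class CorrelationProfile:
    """Per-wavelength Pearson correlation with one quality parameter.

    Constant reflectance columns get ``r = nan`` (undefined) and are
    excluded from any later thresholding.
    """

    wavelengths: np.ndarray
    r: np.ndarray
    parameter: str

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.wavelengths.shape != self.r.shape:
            raise ValueError("wavelengths and r must have equal length")
        finite = self.r[np.isfinite(self.r)]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ValueError("|r| must be <= 1")


@dataclass
class WavelengthSelection:
    """Ordered grid indices retained by one reduction method."""

    indices: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    region_name: str = ""
    wavelengths: np.ndarray | None = None  # physical nm values of the indices

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise EmptySelectionError(f"empty selection for method '{self.method}'")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")
        if self.indices[0] < 0:
            raise ValueError("selection indices must be non-negative")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.size != self.indices.size:
                raise ValueError("wavelengths must align with indices")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class ExtremaProfile:
    """Alternating peak/trough positions (grid indices) on the mean spectrum."""

    positions: np.ndarray
    kinds: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        if self.positions.size != len(self.kinds):
            raise ValueError("positions and kinds must align")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("extrema positions must be strictly increasing")
        for k in self.kinds:
            if k not in ("peak", "trough"):
                raise ValueError(f"unknown extremum kind '{k}'")
        for a, b in zip(self.kinds, self.kinds[1:]):
            if a == b:
                raise ValueError("extrema kinds must strictly alternate")

    @property
    def n_peaks(self) -> int:
        return sum(k == "peak" for k in self.kinds)

    @property
    def n_troughs(self) -> int:
        return sum(k == "trough" for k in self.kinds)

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class JFPTFeatures:
    """Per-sample peak-minus-trough reflectance jumps.

    With P peaks and T troughs alternating there are P + T - 1 jumps; each
    jump pairs a peak with one adjacent trough and its value is
    ``reflectance(peak) - reflectance(trough)``.
    """

    values: np.ndarray
    jump_labels: list[tuple[float, float]]  # (peak nm, trough nm) per jump

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.jump_labels):
            raise ValueError("values columns must align with jump_labels")

    @property
    def n_jumps(self) -> int:
        return len(self.jump_labels)


# ---------------------------------------------------------------------------
# Correlation-threshold band extraction


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r of X against y; constant columns -> nan."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return np.clip(r, -1.0, 1.0)  # nan propagates through clip


class CorrelationSelector(TransformerMixin, BaseEstimator):
    """Keep wavelengths whose |Pearson r| with the target meets a threshold.

    Ties at the boundary are included (``|r| >= threshold``).
    """

    def __init__(self, threshold: float = 0.3):
        self.threshold = threshold

    def fit(self, X, y):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        X, y = check_X_y(X, y)
        if np.ptp(y) == 0:
            raise ValueError("target is constant: correlation undefined")
        self.r_ = _pearson_columns(X, y)
        n_undef = int(np.isnan(self.r_).sum())
        if n_undef:
            logger.warning("%d constant wavelength columns excluded", n_undef)
        with np.errstate(invalid="ignore"):
            self.support_ = np.abs(self.r_) >= self.threshold
        self.support_ &= np.isfinite(self.r_)
        if not self.support_.any():
            raise EmptySelectionError(
                f"no wavelength reaches |r| >= {self.threshold}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self)
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return X[:, self.support_]


def correlation_profile(
    spectra: SpectraSet, quality: QualityTable, parameter: str
) -> CorrelationProfile:
    """Pearson r between every wavelength's reflectance and one target."""
    if spectra.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation profile")
    y = quality.aligned_to(spectra).values_for(parameter)
    if np.ptp(y) == 0:
        raise ValueError(f"'{parameter}' is constant: correlation undefined")
    r = _pearson_columns(spectra.reflectance, y)
    return CorrelationProfile(spectra.wavelengths, r, parameter)


def select_by_correlation(
    profile: CorrelationProfile, threshold: float
) -> WavelengthSelection:
    """Indices where |r| >= threshold, in grid order."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    with np.errstate(invalid="ignore"):
        mask = np.abs(profile.r) >= threshold
    mask &= np.isfinite(profile.r)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(
            f"no wavelength reaches |r| >= {threshold} for '{profile.parameter}'"
        )
    return WavelengthSelection(
        idx,
        method="correlation",
        params={"threshold": threshold, "parameter": profile.parameter},
        wavelengths=profile.wavelengths[idx],
    )


# ---------------------------------------------------------------------------
# Sampling-interval shortening (decimation)


class IntervalDecimator(TransformerMixin, BaseEstimator):
    """Keep every k-th wavelength: grid indices k-1, 2k-1, 3k-1, ...

    Yields exactly ``floor(p / k)`` of the original p wavelengths.
    """

    def __init__(self, k: int = 2):
        self.k = k

    def fit(self, X, y=None):
        X = check_array(X)
        p = X.shape[1]
        if not 1 <= self.k <= p:
            raise ValueError(f"k must lie in [1, {p}], got {self.k}")
        self.indices_ = np.arange(self.k - 1, p, self.k)
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return X[:, self.indices_]


def decimate(spectra: SpectraSet, k: int) -> tuple[SpectraSet, WavelengthSelection]:
    """Emulate a coarser instrument by keeping one wavelength in every k."""
    dec = IntervalDecimator(k=k).fit(spectra.reflectance)
    idx = dec.indices_
    sel = WavelengthSelection(
        idx,
        method="decimation",
        params={"k": k},
        region_name=spectra.region_name,
        wavelengths=spectra.wavelengths[idx],
    )
    return spectra.select_wavelengths(idx), sel


# ---------------------------------------------------------------------------
# Bidirectional stepwise regression


class StepwiseSelector(TransformerMixin, BaseEstimator):
    """Bidirectional stepwise MLR wavelength selection by partial-F tests.

    At each step the excluded wavelength with the smallest partial-F
    p-value enters if below ``alpha_enter``; then any included wavelength
    whose p-value exceeds ``alpha_remove`` is dropped (worst first). Stops
    when no move is possible or after ``max_steps`` entry steps.

    Near-collinear candidates (residual norm below ``collinear_tol`` times
    the column norm after projecting out the current design) are skipped,
    so perfectly duplicated wavelengths are never both selected.
    """

    def __init__(
        self,
        alpha_enter: float = 0.05,
        alpha_remove: float = 0.10,
        max_steps: int = 30,
        collinear_tol: float = 1e-8,
    ):
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove
        self.max_steps = max_steps
        self.collinear_tol = collinear_tol

    def fit(self, X, y):
        if self.alpha_enter > self.alpha_remove:
            raise ValueError("alpha_enter must be <= alpha_remove")
        X, y = check_X_y(X, y)
        n, p = X.shape
        included: list[int] = []
        col_norm = np.sqrt((X * X).sum(axis=0))
        col_norm[col_norm == 0] = 1.0
        yc = y - y.mean()
        tss = float(yc @ yc)

        for _ in range(self.max_steps):
            moved = False
            k = len(included)
            df = n - k - 2  # residual df after adding one more column
            if df < 1 or k >= p:
                break
            D = np.column_stack([np.ones(n)] + [X[:, j] for j in included])
            Q, _ = np.linalg.qr(D)
            yr = y - Q @ (Q.T @ y)
            rss = float(yr @ yr)
            excluded = np.setdiff1d(np.arange(p), included)
            Xe = X[:, excluded]
            Xr = Xe - Q @ (Q.T @ Xe)
            s2 = (Xr * Xr).sum(axis=0)
            ok = np.sqrt(s2) > self.collinear_tol * col_norm[excluded]
            if (~ok).any():
                logger.debug("skipping %d collinear candidates", int((~ok).sum()))
            if not ok.any() or rss <= 1e-12 * max(tss, 1e-300):
                break  # numerically perfect fit: nothing left to explain
            gain = np.full(excluded.size, -np.inf)
            gain[ok] = (Xr[:, ok].T @ yr) ** 2 / s2[ok]
            rss_new = np.maximum(rss - gain, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = gain / (rss_new / df)
            pvals = stats.f.sf(F, 1, df)
            pvals[~ok] = np.inf
            best = int(np.argmin(pvals))
            if pvals[best] < self.alpha_enter:
                included.append(int(excluded[best]))
                included.sort()
                moved = True
            # Backward removals until all included are significant.
            while len(included) > 0:
                worst, pval = self._worst_included(X, y, included)
                if pval > self.alpha_remove:
                    included.remove(worst)
                    moved = True
                else:
                    break
            if not moved:
                break

        if not included:
            raise EmptySelectionError(
                f"no wavelength entered at alpha_enter={self.alpha_enter}"
            )
        self.selected_indices_ = np.asarray(sorted(included), dtype=int)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.selected_indices_] = True
        self.n_features_in_ = p
        return self

    @staticmethod
    def _worst_included(X, y, included):
        """(index, partial-F p-value) of the least significant included var."""
        n = X.shape[0]
        D = np.column_stack([np.ones(n), X[:, included]])
        dfres = n - D.shape[1]
        beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        s2 = float(resid @ resid) / max(dfres, 1)
        cov = s2 * np.linalg.pinv(D.T @ D)
        se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
        t2 = (beta / se) ** 2
        pv = stats.f.sf(t2[1:], 1, max(dfres, 1))  # skip intercept
        worst = int(np.argmax(pv))
        return included[worst], float(pv[worst])

    def get_support(self, indices: bool = False):
        check_is_fitted(self)
        return self.selected_indices_.copy() if indices else self.support_.copy()

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return X[:, self.support_]


def stepwise_select(
    spectra: SpectraSet,
    quality: QualityTable,
    parameter: str,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_steps: int = 30,
) -> WavelengthSelection:
    """Stepwise-regression wavelength selection for one quality parameter."""
    y = quality.aligned_to(spectra).values_for(parameter)
    est = StepwiseSelector(
        alpha_enter=alpha_enter, alpha_remove=alpha_remove, max_steps=max_steps
    ).fit(spectra.reflectance, y)
    idx = est.selected_indices_
    return WavelengthSelection(
        idx,
        method="stepwise",
        params={
            "alpha_enter": alpha_enter,
            "alpha_remove": alpha_remove,
            "parameter": parameter,
        },
        region_name=spectra.region_name,
        wavelengths=spectra.wavelengths[idx],
    )


# ---------------------------------------------------------------------------
# Peak/trough detection and JFPT extraction


def _alternate(positions: np.ndarray, kinds: list[str], values: np.ndarray):
    """Enforce peak/trough alternation, keeping the more extreme of any
    run of consecutive same-kind extrema."""
    out_pos: list[int] = []
    out_kind: list[str] = []
    for pos, kind in zip(positions, kinds):
        if out_kind and out_kind[-1] == kind:
            prev = out_pos[-1]
            better = (
                values[pos] > values[prev]
                if kind == "peak"
                else values[pos] < values[prev]
            )
            if better:
                out_pos[-1] = int(pos)
        else:
            out_pos.append(int(pos))
            out_kind.append(kind)
    return np.asarray(out_pos, dtype=int), out_kind


def detect_extrema(
    spectra: SpectraSet,
    min_prominence: float | None = None,
    presmooth: PretreatmentSpec | None = None,
) -> ExtremaProfile:
    """Locate alternating peaks and troughs on the mean calibration spectrum.

    Candidate extrema are first-difference sign changes of the (optionally
    Savitzky-Golay pre-smoothed) mean spectrum; candidates with prominence
    below ``min_prominence`` are discarded. The default prominence floor is
    twice the median absolute successive difference of the mean spectrum —
    scale-adaptive, so instrument units do not matter. Positions are grid
    indices shared by all samples.
    """
    if spectra.n_wavelengths < 5:
        raise ValueError("need at least 5 wavelengths to detect extrema")
    m = spectra.reflectance.mean(axis=0)
    if presmooth is not None and presmooth.method == "sg":
        m = SavitzkyGolay(presmooth.sg_window, presmooth.sg_order).fit_transform(
            m[None, :]
        )[0]
    if min_prominence is None:
        min_prominence = 2.0 * float(np.median(np.abs(np.diff(m))))
    peaks, _ = find_peaks(m)
    troughs, _ = find_peaks(-m)
    keep_p = peaks[peak_prominences(m, peaks)[0] >= min_prominence] if peaks.size else peaks
    keep_t = (
        troughs[peak_prominences(-m, troughs)[0] >= min_prominence]
        if troughs.size
        else troughs
    )
    pos = np.concatenate([keep_p, keep_t])
    kinds = ["peak"] * keep_p.size + ["trough"] * keep_t.size
    order = np.argsort(pos)
    pos, kinds = pos[order], [kinds[i] for i in order]
    pos, kinds = _alternate(pos, kinds, m)
    if pos.size < 2:
        raise NoStructureError(
            f"only {pos.size} extremum above prominence {min_prominence:.4g}"
        )
    return ExtremaProfile(pos, kinds)


def extract_jfpt(spectra: SpectraSet, extrema: ExtremaProfile) -> JFPTFeatures:
    """Peak-to-trough jump features for every sample.

    For each adjacent (peak, trough) pair along the profile the feature is
    ``reflectance(peak) - reflectance(trough)``, giving ``len(extrema) - 1``
    features. Offsets added to a whole spectrum cancel in the differences.
    """
    if len(extrema) < 2:
        raise ValueError("need at least 2 extrema to form jumps")
    R = spectra.reflectance
    wl = spectra.wavelengths
    cols = []
    labels: list[tuple[float, float]] = []
    for (p1, k1), (p2, k2) in zip(
        zip(extrema.positions, extrema.kinds),
        zip(extrema.positions[1:], extrema.kinds[1:]),
    ):
        peak_i, trough_i = (p1, p2) if k1 == "peak" else (p2, p1)
        cols.append(R[:, peak_i] - R[:, trough_i])
        labels.append((float(wl[peak_i]), float(wl[trough_i])))
    return JFPTFeatures(np.column_stack(cols), labels)


class JFPTExtractor(TransformerMixin, BaseEstimator):
    """Transformer form of JFPT: learn extrema on the fit-set mean spectrum,
    then emit per-sample peak-minus-trough jumps."""

    def __init__(
        self,
        min_prominence: float | None = None,
        presmooth_window: int | None = None,
        presmooth_order: int = 2,
    ):
        self.min_prominence = min_prominence
        self.presmooth_window = presmooth_window
        self.presmooth_order = presmooth_order

    def _spectra(self, X) -> SpectraSet:
        return SpectraSet(np.arange(X.shape[1], dtype=float), X)

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=5)
        presmooth = (
            PretreatmentSpec("sg", self.presmooth_window, self.presmooth_order)
            if self.presmooth_window
            else None
        )
        self.extrema_ = detect_extrema(
            self._spectra(X), self.min_prominence, presmooth
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=5)
        return extract_jfpt(self._spectra(X), self.extrema_).values
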