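"""Calibration models (PLSR, MLR), sample splitting, and evaluation.

The evaluation quadruple follows chemometrics convention: R_C and R_P are
Pearson correlations between predicted and measured values on the
calibration and prediction sets; SEC and SEP are the corresponding root
mean square errors (plain RMSE, no degrees-of-freedom correction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import qr as scipy_qr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .containers import SpectraSet
from .exceptions import RankExhaustedError, SingularDesignError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Estimators


class PLSCalibrator(RegressorMixin, BaseEstimator):
    """PLS1 calibration (NIPALS, mean-centering only, no variance scaling).

    Thin regressor around :class:`sklearn.cross_decomposition.PLSRegression`
    with ``scale=False``: spectra already share a common scale, so only
    centering is applied before component extraction. At full rank the
    coefficients coincide with ordinary least squares.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if np.ptp(y) == 0:
            raise ValueError("invalid target: y has zero variance")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        limit = min(X.shape[0] - 1, X.shape[1])
        if self.n_components > limit:
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n-1, p)={limit}"
            )
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                self._pls.fit(X, y)
                collapsed = False
            except StopIteration:
                collapsed = True
        if not collapsed:
            norms = np.linalg.norm(self._pls.x_scores_, axis=0)
            achievable = int((norms > 1e-10 * max(norms.max(), 1e-300)).sum())
            collapsed = achievable < self.n_components or not np.all(
                np.isfinite(self._pls.coef_)
            )
        if collapsed:
            rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
            raise RankExhaustedError(
                f"component extraction collapses after {rank} components "
                f"(requested {self.n_components})"
            )
        self.coef_ = self._pls.coef_.ravel().copy()
        # Compose the original-scale intercept: sklearn's PLS keeps the
        # centering means internal and applies them inside predict().
        self.intercept_ = float(
            self._pls.intercept_.ravel()[0] - self._pls._x_mean @ self.coef_
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_


class MLRCalibrator(RegressorMixin, BaseEstimator):
    """Multiple linear regression (ordinary least squares with intercept).

    Requires more samples than features plus one and a full-column-rank
    design; rank deficiency raises :class:`SingularDesignError` naming the
    dependent columns.
    """

    def __init__(self, rank_tol: float = 1e-8):
        self.rank_tol = rank_tol

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(f"need more than p+1={p + 1} samples, got {n}")
        D = np.column_stack([np.ones(n), X])
        _, Rm, piv = scipy_qr(D, mode="economic", pivoting=True)
        diag = np.abs(np.diag(Rm))
        bad = diag < self.rank_tol * diag.max()
        if bad.any():
            cols = sorted(int(piv[i]) - 1 for i in np.flatnonzero(bad))
            raise SingularDesignError(
                f"design is rank deficient; dependent feature columns {cols}"
            )
        beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_


def fit_plsr(X, y, n_latent: int) -> PLSCalibrator:
    """Fit a PLS1 calibration with ``n_latent`` components."""
    return PLSCalibrator(n_components=n_latent).fit(X, y)


def fit_mlr(X, y) -> MLRCalibrator:
    """Fit an ordinary-least-squares calibration with intercept."""
    return MLRCalibrator().fit(X, y)


def choose_n_latent(
    X,
    y,
    max_latent: int = 15,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick the PLS component count by k-fold CV with the one-SE rule.

    Returns the smallest component count whose cross-validated RMSE is
    within one standard error of the global minimum — the most parsimonious
    model statistically indistinguishable from the best one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n, p = X.shape
    sample_cap = n - max(2, n // folds) - 1
    cap = min(max_latent, p, sample_cap)
    if sample_cap < max_latent:
        logger.warning("max_latent clipped from %d to %d", max_latent, max(cap, 1))
    elif p < max_latent:
        logger.debug("max_latent limited to %d features", p)
    cap = max(cap, 1)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = np.zeros((folds, cap))  # per-fold mean squared error
    for f, (tr, te) in enumerate(kf.split(X)):
        Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
        pred = np.full(te.size, ytr.mean())
        for a in range(1, cap + 1):
            try:
                model = PLSCalibrator(n_components=a).fit(Xtr, ytr)
                pred = model.predict(Xte)
            except RankExhaustedError:
                pass  # reuse the deepest achievable model's predictions
            sq_err[f, a - 1] = float(np.mean((pred - yte) ** 2))
    rmse = np.sqrt(sq_err.mean(axis=0))
    best = int(np.argmin(rmse))
    se = float(np.std(np.sqrt(sq_err[:, best]), ddof=1) / np.sqrt(folds))
    within = np.flatnonzero(rmse <= rmse[best] + se)
    return int(within[0]) + 1


# ---------------------------------------------------------------------------
# Calibration / prediction splitting


@dataclass
class SplitSpec:
    """How to partition samples into calibration and prediction sets."""

    method: str = "kennard_stone"
    calibration_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kennard_stone", "random"):
            raise ValueError(f"unknown split method '{self.method}'")
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration_fraction must lie in (0, 1)")


def kennard_stone_indices(X: np.ndarray, n_select: int) -> np.ndarray:
    """Deterministic max-min-distance (Kennard-Stone) subset selection.

    Seeds with the two mutually farthest points, then repeatedly adds the
    point whose minimum Euclidean distance to the selected set is largest
    (ties broken by lowest index). Returns sorted row indices.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must lie in [2, {n}]")
    sq = (X * X).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    selected = [min(i, j), max(i, j)]
    min_d = np.minimum(d2[selected[0]], d2[selected[1]])
    while len(selected) < n_select:
        min_d[selected] = -1.0
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, d2[nxt])
    return np.asarray(sorted(selected), dtype=int)


def split_samples(
    spectra: SpectraSet, spec: SplitSpec | None = None
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive calibration/prediction id partition."""
    spec = spec or SplitSpec()
    n = spectra.n_samples
    if n < 8:
        raise ValueError("need at least 8 samples to split")
    n_cal = int(np.floor(spec.calibration_fraction * n))
    if n_cal < 3 or n - n_cal < 3:
        raise ValueError(
            f"fraction {spec.calibration_fraction} leaves fewer than 3 samples in a set"
        )
    if spec.method == "kennard_stone":
        cal_idx = kennard_stone_indices(spectra.reflectance, n_cal)
    else:
        rng = np.random.default_rng(spec.seed)
        cal_idx = np.sort(rng.permutation(n)[:n_cal])
    mask = np.zeros(n, dtype=bool)
    mask[cal_idx] = True
    ids = np.asarray(spectra.sample_ids)
    return ids[mask].tolist(), ids[~mask].tolist()


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class ModelMetrics:
    """The R_C / SEC / R_P / SEP quadruple (errors in target % units)."""

    r_c: float
    sec: float
    r_p: float
    sep: float

    def __post_init__(self) -> None:
        for name in ("r_c", "r_p"):
            v = getattr(self, name)
            if np.isfinite(v) and abs(v) > 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if self.sec < 0 or self.sep < 0:
            raise ValueError("sec/sep must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac, bc = a - a.mean(), b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        return 0.0  # constant side: correlation undefined, reported as 0
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def rmse(measured: np.ndarray, predicted: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(predicted) - np.asarray(measured)) ** 2)))


def evaluate(model, X_cal, y_cal, X_pred, y_pred) -> ModelMetrics:
    """Compute the R_C/SEC/R_P/SEP quadruple for a fitted calibration.

    The caller must build ``X_pred`` with the SAME pretreatment parameters
    and wavelength selection used for ``X_cal``; a feature-count mismatch is
    rejected here as a contract violation.
    """
    X_cal = check_array(X_cal)
    X_pred = check_array(X_pred)
    n_feat = getattr(model, "n_features_in_", X_cal.shape[1])
    if X_cal.shape[1] != n_feat or X_pred.shape[1] != n_feat:
        raise ValueError(
            f"feature dimension mismatch: model expects {n_feat}, got "
            f"calibration {X_cal.shape[1]} / prediction {X_pred.shape[1]}"
        )
    pred_c = model.predict(X_cal)
    pred_p = model.predict(X_pred)
    return ModelMetrics(
        r_c=_pearson(y_cal, pred_c),
        sec=rmse(y_cal, pred_c),
        r_p=_pearson(y_pred, pred_p),
        sep=rmse(y_pred, pred_p),
    )


@dataclass
class CalibrationModel:
    """Serializable record of a fitted calibration (for persistence/CLI)."""

    family: str  # "plsr" | "mlr"
    coefficients: list[float]
    intercept: float
    n_latent: int | None = None
    feature_ref: dict = field(default_factory=dict)
    pretreatment: dict = field(default_factory=dict)
    training_reference: list[float] | None = None

    @classmethod
    def from_estimator(cls, est, **meta) -> "CalibrationModel":
        family = "plsr" if isinstance(est, PLSCalibrator) else "mlr"
        return cls(
            family=family,
            coefficients=[float(c) for c in est.coef_],
            intercept=float(est.intercept_),
            n_latent=est.n_components if family == "plsr" else None,
            **meta,
        )

    def predict(self, X) -> np.ndarray:
        X = check_array(X)
        return X @ np.asarray(self.coefficients) + self.intercept
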