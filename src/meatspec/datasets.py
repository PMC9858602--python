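"""Seeded synthetic VIS/NIR datasets with the structure real lamb spectra show.

The generator produces two-region reflectance matrices plus a composition
table so that every downstream stage (pretreatment, wavelength selection,
calibration) is testable without instrument data.

Forward model
-------------
Per sample *i* the ideal absorbance is a Beer-Lambert mixture of Gaussian
bands plus a smooth baseline,

    A_i(lam) = baseline(lam) + sum_b  strength_b * conc_i(comp_b)
                                      * exp(-(lam - center_b)^2 / (2 width_b^2)),

ideal reflectance ``R_i = 10**(-A_i)``, and the observed spectrum adds
per-sample affine scatter and white noise,

    obs_i = add_i + mult_i * R_i + eps,   mult_i ~ N(1, scatter_mult_sd),
                                          add_i ~ N(0, scatter_add_sd).

The affine scatter is exactly the distortion SNV and MSC are designed to
remove. Myoglobin/oxymyoglobin bands in the visible (415/540/580 nm) are
driven by a latent pigment factor that is independent of the three
composition targets, so visible features are realistic but uninformative
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import QualityTable, SpectraSet
from .exceptions import ConfigError

#: Floor applied to observed reflectance so downstream log/ratio math is safe.
REFLECTANCE_FLOOR = 1e-6

COMPONENTS = ("moisture", "fat", "protein", "pigment")


@dataclass
class CompositionConfig:
    """Population statistics for protein / fat / moisture percentages.

    Defaults reproduce the composition of mixed-cut lamb meat: protein
    mean 19.72 % (CV 6.61 %), strongly right-skewed fat with mean 3.55 %
    and CV 88.42 %, moisture between 64.94 and 78.70 %, and a small
    non-water/protein/fat residual (ash etc., mean 1.70 %) closing the
    mass balance to 100 %.
    """

    protein_mean: float = 19.72
    protein_cv: float = 6.61  # percent of the mean
    protein_range: tuple[float, float] = (14.85, 23.02)
    fat_mean: float = 3.55
    fat_cv: float = 88.42
    fat_range: tuple[float, float] = (0.55, 16.13)
    moisture_range: tuple[float, float] = (64.94, 78.70)
    residual_mean: float = 1.70
    residual_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("protein_range", "fat_range", "moisture_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must have lower < upper, got {(lo, hi)}")
        if not self.protein_range[0] <= self.protein_mean <= self.protein_range[1]:
            raise ConfigError("protein_mean outside protein_range")
        if not self.fat_range[0] <= self.fat_mean <= self.fat_range[1]:
            raise ConfigError("fat_mean outside fat_range")
        if self.residual_mean < 0:
            raise ConfigError("residual_mean must be >= 0")
        if self.protein_cv < 0 or self.fat_cv < 0 or self.residual_sd < 0:
            raise ConfigError("dispersion parameters must be >= 0")
        # Closure feasibility at the means.
        m = 100.0 - self.protein_mean - self.fat_mean - self.residual_mean
        lo, hi = self.moisture_range
        if not lo - 5.0 <= m <= hi + 5.0:
            raise ConfigError(
                f"mean closure gives moisture {m:.2f}%, far outside {self.moisture_range}"
            )

    @property
    def protein_sd(self) -> float:
        return self.protein_mean * self.protein_cv / 100.0


@dataclass
class BandSpec:
    """One Gaussian absorption band tied to a composition component.

    ``strength`` is absorbance units per percentage point of the component
    (for pigment: per unit of the latent factor).
    """

    center: float
    width: float
    strength: float
    component: str

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"band width must be > 0 (center {self.center} nm)")
        if not (400.0 <= self.center <= 1700.0):
            raise ConfigError(
                f"band center {self.center} nm outside the 400-1700 nm instrument union"
            )
        if self.component not in COMPONENTS:
            raise ConfigError(
                f"unknown band component '{self.component}' (expected one of {COMPONENTS})"
            )


@dataclass
class InstrumentConfig:
    """One instrument region: grid plus noise/scatter magnitudes."""

    region_name: str
    wl_start: float
    wl_end: float
    n_points: int
    noise_sd: float = 0.004
    scatter_mult_sd: float = 0.07
    scatter_add_sd: float = 0.012

    def __post_init__(self) -> None:
        if not self.wl_start < self.wl_end:
            raise ConfigError("wl_start must be < wl_end")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        if min(self.noise_sd, self.scatter_mult_sd, self.scatter_add_sd) < 0:
            raise ConfigError("noise/scatter standard deviations must be >= 0")

    def grid(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_end, self.n_points)


def default_instruments() -> tuple[InstrumentConfig, InstrumentConfig]:
    """The two study regions.

    Region 1: 400-1050 nm with 1130 points (0.5757 nm spacing). Region 2:
    900-1700 nm with 125 points (6.452 nm spacing; both endpoints kept).
    """
    return (
        InstrumentConfig("region1", 400.0, 1050.0, 1130),
        InstrumentConfig("region2", 900.0, 1700.0, 125),
    )


def default_bands() -> list[BandSpec]:
    """Absorption bands of meat constituents across 400-1700 nm.

    Water (O-H overtones) at 760 / 980 / 1450 nm; fat (C-H overtones)
    at 960 / 1180 / 1210 nm; protein (N-H overtones) at 910 / 1080 /
    1450 nm (the 1450 nm region mixes O-H and N-H); myoglobin and
    oxymyoglobin Soret/Q bands at 415 / 540 / 580 nm, driven by the
    latent pigment factor.
    """
    return [
        BandSpec(415.0, 12.0, 0.30, "pigment"),
        BandSpec(540.0, 11.0, 0.13, "pigment"),
        BandSpec(580.0, 11.0, 0.12, "pigment"),
        BandSpec(760.0, 22.0, 0.0016, "moisture"),
        BandSpec(980.0, 28.0, 0.0042, "moisture"),
        BandSpec(1450.0, 42.0, 0.0110, "moisture"),
        BandSpec(960.0, 24.0, 0.0045, "fat"),
        BandSpec(1180.0, 32.0, 0.0160, "fat"),
        BandSpec(1210.0, 26.0, 0.0140, "fat"),
        BandSpec(910.0, 28.0, 0.0060, "protein"),
        BandSpec(1080.0, 32.0, 0.0110, "protein"),
        BandSpec(1450.0, 50.0, 0.0040, "protein"),
    ]


#: Latent pigment factor dispersion (lognormal sigma of a mean-1 factor).
_PIGMENT_SIGMA = 0.18


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; exact point mass when sd == 0."""
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ConfigError("degenerate draw outside its truncation range")
        return np.full(n, mean)
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise ConfigError(f"truncated normal({mean}, {sd}) on [{lo}, {hi}] is infeasible")


def _truncated_lognormal_moments(
    mu: float, sigma: float, lo: float, hi: float
) -> tuple[float, float]:
    """(mean, CV) of a lognormal(mu, sigma) truncated to [lo, hi]."""
    from scipy.stats import norm as _norm

    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    Z = _norm.cdf(b) - _norm.cdf(a)
    if Z < 1e-14:
        # Mass escaped the window: report the boundary it collapsed onto.
        edge = hi if b < 0 else lo
        return edge, 0.0
    m1 = np.exp(mu + sigma**2 / 2) * (_norm.cdf(b - sigma) - _norm.cdf(a - sigma)) / Z
    m2 = (
        np.exp(2 * mu + 2 * sigma**2)
        * (_norm.cdf(b - 2 * sigma) - _norm.cdf(a - 2 * sigma))
        / Z
    )
    return float(m1), float(np.sqrt(max(m2 - m1**2, 0.0)) / m1)


def _lognormal_params_for_truncated(
    mean: float, cv: float, lo: float, hi: float
) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose [lo, hi]-truncation has the given mean/CV.

    Solved by nested root finding: for each sigma, mu is chosen so the
    truncated mean matches, then sigma is chosen so the truncated CV
    matches. Infeasible targets raise :class:`ConfigError`.
    """
    from scipy.optimize import brentq

    def mu_for(sigma: float) -> float:
        return brentq(
            lambda mu: _truncated_lognormal_moments(mu, sigma, lo, hi)[0] - mean,
            -20.0,
            20.0,
            xtol=1e-12,
        )

    def cv_gap(sigma: float) -> float:
        return _truncated_lognormal_moments(mu_for(sigma), sigma, lo, hi)[1] - cv

    try:
        sigma = brentq(cv_gap, 1e-3, 5.0, xtol=1e-10)
    except ValueError:
        raise ConfigError(
            f"no truncated lognormal on [{lo}, {hi}] attains mean {mean} with CV {cv}"
        )
    return mu_for(sigma), sigma


def _truncated_lognormal(
    rng: np.random.Generator,
    mean: float,
    cv_percent: float,
    lo: float,
    hi: np.ndarray,
    n: int,
) -> np.ndarray:
    """Lognormal draws truncated to [lo, hi_i] (hi may vary per sample).

    (mu, sigma) are calibrated so the nominal-range truncation itself has
    the requested mean and CV; out-of-range draws are rejected and redrawn.
    The few samples with tighter per-sample bounds add a small extra bias.
    """
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (n,))
    if np.any(hi < lo):
        raise ConfigError("fat truncation range collapsed (hi < lo); closure infeasible")
    cv = cv_percent / 100.0
    if cv == 0.0:
        return np.minimum(np.maximum(np.full(n, mean), lo), hi)
    mu, sigma = _lognormal_params_for_truncated(mean, cv, lo, float(hi.max()))
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        draw = rng.lognormal(mu, sigma, size=todo.size)
        ok = (draw >= lo) & (draw <= hi[todo])
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise ConfigError("truncated lognormal sampling failed to converge")


def sample_compositions(n: int, cfg: CompositionConfig | None = None) -> QualityTable:
    """Draw ``n`` protein/fat/moisture compositions closing to 100 %.

    Protein is truncated normal; fat is a truncated moment-matched
    lognormal whose per-sample upper bound additionally enforces
    ``moisture >= moisture_range[0]`` through the closure; moisture is the
    closure remainder ``100 - protein - fat - residual``, clipped at the
    top of its range with the residual absorbing the clip.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    cfg = cfg or CompositionConfig()
    rng = np.random.default_rng(cfg.seed)
    protein = _truncated_normal(
        rng, cfg.protein_mean, cfg.protein_sd, *cfg.protein_range, n
    )
    residual = _truncated_normal(
        rng, cfg.residual_mean, cfg.residual_sd, 0.0, cfg.residual_mean + 8 * max(cfg.residual_sd, 1e-12), n
    ) if cfg.residual_sd > 0 else np.full(n, cfg.residual_mean)
    # Fat upper bound keeps closure moisture above its range floor.
    fat_hi = np.minimum(
        cfg.fat_range[1], 100.0 - protein - residual - cfg.moisture_range[0]
    )
    fat = _truncated_lognormal(rng, cfg.fat_mean, cfg.fat_cv, cfg.fat_range[0], fat_hi, n)
    moisture = 100.0 - protein - fat - residual
    over = moisture > cfg.moisture_range[1]
    moisture = np.where(over, cfg.moisture_range[1], moisture)  # residual absorbs
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1}" for i in range(n)],
            "protein": protein,
            "fat": fat,
            "moisture": moisture,
        }
    )
    return QualityTable(df)


def _baseline_absorbance(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth instrument/tissue baseline, gently decreasing with wavelength."""
    t = (wavelengths - 400.0) / 1300.0
    return 0.42 - 0.25 * t + 0.10 * t * t


def generate_spectra(
    quality: QualityTable,
    bands: list[BandSpec] | None = None,
    instr: InstrumentConfig | None = None,
    seed: int = 0,
) -> SpectraSet:
    """Simulate one region's observed reflectance for every sample.

    See the module docstring for the forward model. Deterministic under
    ``seed``; all outputs are clipped at :data:`REFLECTANCE_FLOOR`.
    """
    if len(quality) == 0:
        raise ValueError("quality table is empty")
    bands = default_bands() if bands is None else bands
    instr = instr or default_instruments()[0]
    wl = instr.grid()
    in_range = [b for b in bands if instr.wl_start - 3 * b.width <= b.center <= instr.wl_end + 3 * b.width]
    components_present = {b.component for b in bands}
    for comp in components_present:
        if comp == "pigment":
            continue
        if comp not in quality.data.columns:
            raise ConfigError(f"band component '{comp}' missing from quality table")

    n = len(quality)
    rng = np.random.default_rng(seed)
    # Latent pigment factor: mean-1 lognormal, independent of the targets.
    pigment = rng.lognormal(-_PIGMENT_SIGMA**2 / 2.0, _PIGMENT_SIGMA, size=n)
    conc = {
        "moisture": quality.values_for("moisture"),
        "fat": quality.values_for("fat"),
        "protein": quality.values_for("protein"),
        "pigment": pigment,
    }
    absorb = np.tile(_baseline_absorbance(wl), (n, 1))
    for b in in_range:
        shape = np.exp(-0.5 * ((wl - b.center) / b.width) ** 2)
        absorb += b.strength * np.outer(conc[b.component], shape)
    ideal = 10.0 ** (-absorb)
    mult = rng.normal(1.0, instr.scatter_mult_sd, size=n)
    add = rng.normal(0.0, instr.scatter_add_sd, size=n)
    noise = rng.normal(0.0, instr.noise_sd, size=(n, wl.size))
    observed = add[:, None] + mult[:, None] * ideal + noise
    observed = np.maximum(observed, REFLECTANCE_FLOOR)
    return SpectraSet(
        wavelengths=wl,
        reflectance=observed,
        sample_ids=quality.sample_ids,
        region_name=instr.region_name,
    )


@dataclass
class StudyDataset:
    """Bundle of both instrument regions sharing one composition table."""

    region1: SpectraSet
    region2: SpectraSet
    quality: QualityTable

    def __post_init__(self) -> None:
        if not (
            self.region1.sample_ids == self.region2.sample_ids == self.quality.sample_ids
        ):
            raise ValueError("regions and quality table must share sample ids in order")


def make_study_dataset(
    n: int = 150,
    seed: int = 0,
    composition: CompositionConfig | None = None,
    bands: list[BandSpec] | None = None,
    instruments: tuple[InstrumentConfig, InstrumentConfig] | None = None,
) -> StudyDataset:
    """Generate the full two-region study dataset (default n = 150).

    Both regions are generated from the SAME composition table; the three
    child seeds are derived deterministically from ``seed``.
    """
    if n < 10:
        raise ValueError("need n >= 10 samples for modeling use")
    instruments = instruments or default_instruments()
    composition = composition or CompositionConfig()
    ss = np.random.SeedSequence(seed)
    s_comp, s_r1, s_r2 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    cfg = CompositionConfig(**{**composition.__dict__, "seed": s_comp})
    quality = sample_compositions(n, cfg)
    region1 = generate_spectra(quality, bands, instruments[0], seed=s_r1)
    region2 = generate_spectra(quality, bands, instruments[1], seed=s_r2)
    return StudyDataset(region1, region2, quality)
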