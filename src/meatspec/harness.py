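"""Comparative study harness: pretreatment x region x target model grids.

Reproduces the structure of the comparison the package exists for:

* full-spectrum PLSR under four pretreatments (raw / SNV / S-G / MSC),
* PLSR on correlation-thresholded bands,
* MLR on stepwise-selected wavelengths and on JFPT jump features
  (both on untreated spectra),
* a PLSR sweep over decimation factors (default target: fat).

One Kennard-Stone calibration/prediction split is computed per dataset and
shared by every cell, so method comparisons are paired. All
calibration-derived statistics (MSC reference, correlation profiles,
extrema positions, stepwise selections) come from the calibration set only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import QualityTable, SpectraSet, TARGETS
from .datasets import StudyDataset
from .exceptions import MeatspecError
from .modeling import (
    MLRCalibrator,
    ModelMetrics,
    PLSCalibrator,
    SplitSpec,
    choose_n_latent,
    evaluate,
    split_samples,
)
from .preprocessing import PretreatmentSpec, make_transformer
from .reduction import (
    correlation_profile,
    detect_extrema,
    extract_jfpt,
    select_by_correlation,
    stepwise_select,
)

logger = logging.getLogger(__name__)

DEFAULT_PRETREATMENTS = ("raw", "snv", "sg", "msc")

#: Correlation thresholds per region (region 2's weaker correlations get
#: lower cutoffs).
DEFAULT_THRESHOLDS = {"region1": (0.3, 0.4, 0.5), "region2": (0.1, 0.2, 0.3)}

#: Decimation factor lists per region (k = 1 anchors the full spectrum).
DEFAULT_FACTORS = {
    "region1": (1, 2, 3, 4, 10, 12, 20, 30, 40, 50, 60, 70, 80, 90, 100),
    "region2": tuple(range(1, 25)),
}

#: Savitzky-Golay window per region: ~6 nm on the dense grid, ~26 nm on the
#: coarse one — wide enough to smooth, narrower than the absorption bands.
SG_WINDOWS = {"region1": 11, "region2": 5}


@dataclass
class StudyRecord:
    """One model cell of a comparison table."""

    region_name: str
    target: str
    pretreatment: str
    reduction_method: str  # "full", "correlation", "stepwise", "decimation", "jfpt"
    method_params: dict = field(default_factory=dict)
    n_features: int = 0
    n_latent: int | None = None
    metrics: ModelMetrics | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = self.metrics.to_dict() if self.metrics else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyRecord":
        d = dict(d)
        if d.get("metrics"):
            d["metrics"] = ModelMetrics(**d["metrics"])
        return cls(**d)


@dataclass
class SweepResult:
    """One decimation-sweep point: metrics per pretreatment at factor k."""

    region_name: str
    k: int
    n_features: int
    metrics: dict = field(default_factory=dict)  # pretreatment -> ModelMetrics

    def to_dict(self) -> dict:
        return {
            "region_name": self.region_name,
            "k": self.k,
            "n_features": self.n_features,
            "metrics": {m: v.to_dict() for m, v in self.metrics.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepResult":
        return cls(
            region_name=d["region_name"],
            k=int(d["k"]),
            n_features=int(d["n_features"]),
            metrics={m: ModelMetrics(**v) for m, v in d["metrics"].items()},
        )


def _pretreatment_spec(method: str, region_name: str) -> PretreatmentSpec:
    return PretreatmentSpec(method=method, sg_window=SG_WINDOWS.get(region_name, 11))


def make_split(
    dataset: StudyDataset, spec: SplitSpec | None = None
) -> tuple[list[str], list[str]]:
    """One shared calibration/prediction split, computed on region-1 raw spectra."""
    return split_samples(dataset.region1, spec or SplitSpec())


def _cell_arrays(
    spectra: SpectraSet,
    quality: QualityTable,
    target: str,
    cal_ids: list[str],
    pred_ids: list[str],
    pretreatment: PretreatmentSpec,
):
    """Pretreat (fit on calibration only) and split into cal/pred arrays."""
    cal = spectra.select_samples(cal_ids)
    pred = spectra.select_samples(pred_ids)
    tf = make_transformer(pretreatment).fit(cal.reflectance)
    X_cal = tf.transform(cal.reflectance)
    X_pred = tf.transform(pred.reflectance)
    y_cal = quality.select_samples(cal_ids).values_for(target)
    y_pred = quality.select_samples(pred_ids).values_for(target)
    return X_cal, y_cal, X_pred, y_pred, cal


def _plsr_cell(X_cal, y_cal, X_pred, y_pred, seed: int, max_latent: int = 15):
    n_latent = choose_n_latent(X_cal, y_cal, max_latent=max_latent, seed=seed)
    model = PLSCalibrator(n_components=n_latent).fit(X_cal, y_cal)
    return n_latent, evaluate(model, X_cal, y_cal, X_pred, y_pred)


def run_fullspectrum_grid(
    dataset: StudyDataset,
    targets=TARGETS,
    pretreatments=DEFAULT_PRETREATMENTS,
    split: SplitSpec | None = None,
    seed: int = 0,
) -> list[StudyRecord]:
    """PLSR on the full spectrum of each region under each pretreatment.

    The default design yields 2 regions x 3 targets x 4 pretreatments = 24
    records. Failed cells are recorded with an error marker, never dropped.
    """
    cal_ids, pred_ids = make_split(dataset, split)
    records = []
    for spectra in (dataset.region1, dataset.region2):
        for target in targets:
            for method in pretreatments:
                spec = _pretreatment_spec(method, spectra.region_name)
                rec = StudyRecord(
                    region_name=spectra.region_name,
                    target=target,
                    pretreatment=method,
                    reduction_method="full",
                    n_features=spectra.n_wavelengths,
                )
                try:
                    X_cal, y_cal, X_pred, y_pred, _ = _cell_arrays(
                        spectra, dataset.quality, target, cal_ids, pred_ids, spec
                    )
                    rec.n_latent, rec.metrics = _plsr_cell(
                        X_cal, y_cal, X_pred, y_pred, seed
                    )
                except MeatspecError as err:
                    rec.error = str(err)
                    logger.warning("cell failed: %s", err)
                records.append(rec)
    return records


def run_correlation_grid(
    dataset: StudyDataset,
    thresholds_by_region: dict | None = None,
    targets=TARGETS,
    split: SplitSpec | None = None,
    seed: int = 0,
) -> list[StudyRecord]:
    """PLSR on correlation-thresholded bands (profile from calibration only).

    Spectra are MSC-corrected (against the calibration mean) before the
    correlation profile is computed, so scatter does not masquerade as
    chemical correlation. Default design: 2 x 3 x 3 = 18 records.
    """
    thresholds_by_region = thresholds_by_region or DEFAULT_THRESHOLDS
    cal_ids, pred_ids = make_split(dataset, split)
    records = []
    for spectra in (dataset.region1, dataset.region2):
        thresholds = thresholds_by_region[spectra.region_name]
        spec = PretreatmentSpec(method="msc")
        for target in targets:
            X_cal, y_cal, X_pred, y_pred, cal = _cell_arrays(
                spectra, dataset.quality, target, cal_ids, pred_ids, spec
            )
            profile = correlation_profile(
                cal.with_reflectance(X_cal), dataset.quality.select_samples(cal_ids), target
            )
            for threshold in thresholds:
                rec = StudyRecord(
                    region_name=spectra.region_name,
                    target=target,
                    pretreatment="msc",
                    reduction_method="correlation",
                    method_params={"threshold": threshold},
                )
                try:
                    sel = select_by_correlation(profile, threshold)
                    rec.n_features = len(sel)
                    rec.n_latent, rec.metrics = _plsr_cell(
                        X_cal[:, sel.indices], y_cal, X_pred[:, sel.indices], y_pred, seed
                    )
                except MeatspecError as err:
                    rec.error = str(err)
                    logger.warning("cell failed: %s", err)
                records.append(rec)
    return records


def run_selected_feature_models(
    dataset: StudyDataset,
    targets=TARGETS,
    split: SplitSpec | None = None,
    sg_presmooth_for_extrema: bool = True,
) -> list[StudyRecord]:
    """MLR on stepwise-selected wavelengths and on JFPT jump features.

    Both run on untreated (raw) spectra. Stepwise selection and extrema
    detection use the calibration set only. Default design: 2 regions x 3
    targets x 2 methods = 12 records.
    """
    cal_ids, pred_ids = make_split(dataset, split)
    records = []
    for spectra in (dataset.region1, dataset.region2):
        cal = spectra.select_samples(cal_ids)
        pred = spectra.select_samples(pred_ids)
        quality_cal = dataset.quality.select_samples(cal_ids)
        presmooth = (
            _pretreatment_spec("sg", spectra.region_name)
            if sg_presmooth_for_extrema
            else None
        )
        try:
            extrema = detect_extrema(cal, presmooth=presmooth)
        except MeatspecError as err:
            extrema = None
            extrema_error = str(err)
        for target in targets:
            y_cal = quality_cal.values_for(target)
            y_pred = dataset.quality.select_samples(pred_ids).values_for(target)
            # (a) stepwise selection + MLR
            rec = StudyRecord(
                region_name=spectra.region_name,
                target=target,
                pretreatment="raw",
                reduction_method="stepwise",
            )
            try:
                sel = stepwise_select(cal, quality_cal, target)
                rec.n_features = len(sel)
                rec.method_params = {
                    "wavelengths_nm": [round(float(w), 3) for w in sel.wavelengths]
                }
                model = MLRCalibrator().fit(cal.reflectance[:, sel.indices], y_cal)
                rec.metrics = evaluate(
                    model,
                    cal.reflectance[:, sel.indices],
                    y_cal,
                    pred.reflectance[:, sel.indices],
                    y_pred,
                )
            except MeatspecError as err:
                rec.error = str(err)
                logger.warning("cell failed: %s", err)
            records.append(rec)
            # (b) JFPT + MLR
            rec = StudyRecord(
                region_name=spectra.region_name,
                target=target,
                pretreatment="raw",
                reduction_method="jfpt",
            )
            if extrema is None:
                rec.error = extrema_error
            else:
                try:
                    feats_cal = extract_jfpt(cal, extrema)
                    feats_pred = extract_jfpt(pred, extrema)
                    rec.n_features = feats_cal.n_jumps
                    rec.method_params = {
                        "n_peaks": extrema.n_peaks,
                        "n_troughs": extrema.n_troughs,
                    }
                    model = MLRCalibrator().fit(feats_cal.values, y_cal)
                    rec.metrics = evaluate(
                        model, feats_cal.values, y_cal, feats_pred.values, y_pred
                    )
                except MeatspecError as err:
                    rec.error = str(err)
                    logger.warning("cell failed: %s", err)
            records.append(rec)
    return records


def run_decimation_sweep(
    dataset: StudyDataset,
    target: str = "fat",
    factors_by_region: dict | None = None,
    pretreatments=DEFAULT_PRETREATMENTS,
    split: SplitSpec | None = None,
    seed: int = 0,
) -> list[SweepResult]:
    """PLSR metrics versus decimation factor k, per region and pretreatment.

    Decimation precedes pretreatment-free column subsetting of the already
    pretreated matrix, i.e. pretreatments are applied to the decimated grid
    exactly as a coarser instrument would deliver it.
    """
    factors_by_region = factors_by_region or DEFAULT_FACTORS
    cal_ids, pred_ids = make_split(dataset, split)
    results = []
    for spectra in (dataset.region1, dataset.region2):
        p = spectra.n_wavelengths
        for k in factors_by_region[spectra.region_name]:
            if k > p:
                logger.warning(
                    "skipping factor %d > %d wavelengths (%s)", k, p, spectra.region_name
                )
                continue
            idx = np.arange(k - 1, p, k)
            sub = spectra.select_wavelengths(idx)
            point = SweepResult(
                region_name=spectra.region_name, k=int(k), n_features=int(idx.size)
            )
            for method in pretreatments:
                spec = _pretreatment_spec(method, spectra.region_name)
                if spec.method == "sg" and spec.sg_window > idx.size:
                    logger.warning(
                        "skipping S-G at k=%d: window %d > %d points",
                        k,
                        spec.sg_window,
                        idx.size,
                    )
                    continue
                X_cal, y_cal, X_pred, y_pred, _ = _cell_arrays(
                    sub, dataset.quality, target, cal_ids, pred_ids, spec
                )
                _, point.metrics[method] = _plsr_cell(
                    X_cal, y_cal, X_pred, y_pred, seed
                )
            results.append(point)
    return results


# ---------------------------------------------------------------------------
# Reporting


def best_records(records: list[StudyRecord]) -> set[int]:
    """Indices of the best record per (region, target): highest R_P, ties
    broken by lower SEP."""
    best: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(records):
        if rec.metrics is None:
            continue
        key = (rec.region_name, rec.target)
        if key not in best:
            best[key] = i
            continue
        cur = records[best[key]].metrics
        if (rec.metrics.r_p, -rec.metrics.sep) > (cur.r_p, -cur.sep):
            best[key] = i
    return set(best.values())


def render_report(
    records: list[StudyRecord],
    out_dir,
    sweeps: list[SweepResult] | None = None,
) -> list[str]:
    """Write comparison tables (and sweep curves) as deterministic CSV files.

    Returns the paths written. Regenerating from the same records is
    byte-identical.
    """
    import csv
    from pathlib import Path

    if not records:
        raise ValueError("no records to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    table_path = out_dir / "model_table.csv"
    marked = best_records(records)
    with open(table_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "region",
                "target",
                "pretreatment",
                "method",
                "params",
                "n_features",
                "n_latent",
                "r_c",
                "sec",
                "r_p",
                "sep",
                "best",
                "error",
            ]
        )
        for i, rec in enumerate(records):
            m = rec.metrics
            w.writerow(
                [
                    rec.region_name,
                    rec.target,
                    rec.pretreatment,
                    rec.reduction_method,
                    ";".join(f"{k}={v}" for k, v in sorted(rec.method_params.items())),
                    rec.n_features,
                    rec.n_latent if rec.n_latent is not None else "",
                    f"{m.r_c:.4f}" if m else "",
                    f"{m.sec:.4f}" if m else "",
                    f"{m.r_p:.4f}" if m else "",
                    f"{m.sep:.4f}" if m else "",
                    "*" if i in marked else "",
                    rec.error or "",
                ]
            )
    paths.append(str(table_path))

    if sweeps:
        sweep_path = out_dir / "decimation_sweep.csv"
        methods = sorted({m for s in sweeps for m in s.metrics})
        with open(sweep_path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["region", "k", "n_features"]
            for m in methods:
                header += [f"r_c_{m}", f"sec_{m}", f"r_p_{m}", f"sep_{m}"]
            w.writerow(header)
            for s in sorted(sweeps, key=lambda s: (s.region_name, s.k)):
                row = [s.region_name, s.k, s.n_features]
                for m in methods:
                    mm = s.metrics.get(m)
                    row += (
                        [f"{mm.r_c:.4f}", f"{mm.sec:.4f}", f"{mm.r_p:.4f}", f"{mm.sep:.4f}"]
                        if mm
                        else ["", "", "", ""]
                    )
                w.writerow(row)
        paths.append(str(sweep_path))
    return paths
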