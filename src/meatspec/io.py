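"""CSV/JSON readers and writers plus the end-to-end pipeline runner.

Interchange formats (all plain text):

* spectra CSV — header ``sample_id,<wl1>,<wl2>,...`` with wavelengths in nm
  to 3 decimals, reflectance to 6 decimals, one row per sample;
* quality CSV — ``sample_id,protein,fat,moisture`` to 2 decimals;
* selections CSV — ``index,wavelength_nm,method,param``;
* study records — JSON lines, one record per line.

Every persisted pipeline run is stamped with the SHA-256 hash of its
configuration and the seed, so artifacts are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import QualityTable, SpectraSet, TARGETS
from .exceptions import ParseError
from .harness import (
    DEFAULT_PRETREATMENTS,
    StudyRecord,
    render_report,
    run_correlation_grid,
    run_decimation_sweep,
    run_fullspectrum_grid,
    run_selected_feature_models,
)
from .modeling import SplitSpec
from .datasets import make_study_dataset
from .reduction import WavelengthSelection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spectra / quality CSV


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id," + ",".join(f"{w:.3f}" for w in spectra.wavelengths) + "\n")
        for sid, row in zip(spectra.sample_ids, spectra.reflectance):
            fh.write(sid + "," + ",".join(f"{v:.6f}" for v in row) + "\n")


def read_spectra_csv(path, region_name: str = "") -> SpectraSet:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if not header or header[0] != "sample_id":
            raise ParseError(f"{path}:1: header must start with 'sample_id'")
        try:
            wl = np.asarray([float(w) for w in header[1:]])
        except ValueError as err:
            raise ParseError(f"{path}:1: non-numeric wavelength in header ({err})")
        if wl.size < 1:
            raise ParseError(f"{path}:1: no wavelength columns")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ParseError(f"{path}:1: header wavelengths must be strictly increasing")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != wl.size + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {wl.size + 1} fields, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric reflectance value")
            ids.append(parts[0])
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return SpectraSet(wl, np.asarray(rows), ids, region_name=region_name or path.stem)


def write_quality_csv(quality: QualityTable, path) -> None:
    df = quality.data.copy()
    for col in TARGETS:
        df[col] = df[col].map(lambda v: f"{v:.2f}")
    df.to_csv(path, index=False)


def read_quality_csv(path) -> QualityTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty quality file")
    return QualityTable(df)  # QualityTable does per-row validation


# ---------------------------------------------------------------------------
# Selections / records


def write_selection_csv(selection: WavelengthSelection, path) -> None:
    param = ";".join(f"{k}={v}" for k, v in sorted(selection.params.items()))
    with open(path, "w") as fh:
        fh.write("index,wavelength_nm,method,param\n")
        for i, idx in enumerate(selection.indices):
            wl = (
                f"{selection.wavelengths[i]:.3f}"
                if selection.wavelengths is not None
                else ""
            )
            fh.write(f"{idx},{wl},{selection.method},{param}\n")


def read_selection_csv(path) -> WavelengthSelection:
    df = pd.read_csv(path)
    for col in ("index", "wavelength_nm", "method"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    params = {}
    if "param" in df.columns and len(df) and isinstance(df["param"].iloc[0], str):
        for item in df["param"].iloc[0].split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                try:
                    params[k] = float(v)
                except ValueError:
                    params[k] = v
    return WavelengthSelection(
        df["index"].to_numpy(int),
        method=str(df["method"].iloc[0]),
        params=params,
        wavelengths=df["wavelength_nm"].to_numpy(float),
    )


def write_records_jsonl(records: list[StudyRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")


def read_records_jsonl(path) -> list[StudyRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(StudyRecord.from_dict(json.loads(line)))
    return records


# ---------------------------------------------------------------------------
# Pipeline runner


DEFAULT_CONFIG = {
    "n": 150,
    "seed": 0,
    "out_dir": "meatspec_run",
    "split": {"method": "kennard_stone", "calibration_fraction": 0.75, "seed": 0},
    "pretreatments": list(DEFAULT_PRETREATMENTS),
    "sweep_target": "fat",
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    merged = {**DEFAULT_CONFIG, **cfg}
    merged["split"] = {**DEFAULT_CONFIG["split"], **(cfg.get("split") or {})}
    return merged


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Simulate, model and report end to end; returns the artifact manifest.

    Stages: simulate -> split -> (full-spectrum grid, correlation grid,
    selected-feature models, decimation sweep) -> report. Every artifact
    directory gets a ``manifest.json`` with the config hash, seed, stage
    timings and record counts.
    """
    config = {**DEFAULT_CONFIG, **config}
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    split = SplitSpec(**config["split"])
    seed = int(config["seed"])
    timings = {}

    t0 = time.perf_counter()
    dataset = make_study_dataset(n=int(config["n"]), seed=seed)
    write_spectra_csv(dataset.region1, out_dir / "spectra_region1.csv")
    write_spectra_csv(dataset.region2, out_dir / "spectra_region2.csv")
    write_quality_csv(dataset.quality, out_dir / "quality.csv")
    timings["simulate_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    records = run_fullspectrum_grid(dataset, split=split, seed=seed)
    records += run_correlation_grid(dataset, split=split, seed=seed)
    records += run_selected_feature_models(dataset, split=split)
    timings["grids_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    sweeps = run_decimation_sweep(
        dataset, target=config["sweep_target"], split=split, seed=seed
    )
    timings["sweep_s"] = round(time.perf_counter() - t0, 3)

    write_records_jsonl(records, out_dir / "records.jsonl")
    with open(out_dir / "sweep.json", "w") as fh:
        json.dump([s.to_dict() for s in sweeps], fh, sort_keys=True, indent=1)
    paths = render_report(records, out_dir, sweeps=sweeps)

    manifest = {
        "config_hash": config_hash(config),
        "seed": seed,
        "n_records": len(records),
        "n_sweep_points": len(sweeps),
        "n_failed_cells": sum(1 for r in records if r.error),
        "timings": timings,
        "artifacts": sorted(
            str(p.relative_to(out_dir)) for p in out_dir.iterdir() if p.is_file()
        ),
        "report_paths": paths,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    logger.info("pipeline complete: %d records, %d sweep points", len(records), len(sweeps))
    return manifest
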