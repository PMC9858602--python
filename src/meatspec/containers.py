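"""Core in-memory containers: reflectance spectra and composition tables.

A :class:`SpectraSet` holds one instrument region's sample x wavelength
relative-reflectance matrix on a strictly increasing wavelength grid (nm).
A :class:`QualityTable` holds the per-sample protein / fat / moisture
percentages used as calibration targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError

TARGETS = ("protein", "fat", "moisture")


@dataclass
class SpectraSet:
    """Wavelength grid plus aligned sample x wavelength reflectance matrix.

    Parameters
    ----------
    wavelengths : array of float, shape (p,)
        Strictly increasing grid in nm.
    reflectance : array of float, shape (n, p)
        Relative reflectance (dimensionless). Raw instrument output is
        positive; pretreated spectra (e.g. after SNV) may not be, so
        positivity is not enforced here.
    sample_ids : sequence of str, length n
        Unique identifiers aligned to matrix rows.
    region_name : str
        Free-text instrument-region label (e.g. ``"region1"``).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    region_name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"reflectance has {self.reflectance.shape[1]} columns but grid "
                f"has {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.wavelengths)) or not np.all(
            np.isfinite(self.reflectance)
        ):
            raise ValueError("wavelengths and reflectance must be finite")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(self.reflectance.shape[0])]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.reflectance.shape[0]:
            raise ValueError("sample_ids length must equal the number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def with_reflectance(self, matrix: np.ndarray) -> "SpectraSet":
        """Same grid and ids, new reflectance values (e.g. after pretreatment)."""
        return replace(self, reflectance=np.asarray(matrix, dtype=float))

    def select_wavelengths(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            wavelengths=self.wavelengths[idx],
            reflectance=self.reflectance[:, idx],
        )

    def select_samples(self, ids: Sequence[str]) -> "SpectraSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [pos[s] for s in ids]
        return replace(
            self,
            reflectance=self.reflectance[rows],
            sample_ids=[str(s) for s in ids],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.reflectance, columns=[f"{w:.3f}" for w in self.wavelengths]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class QualityTable:
    """Per-sample composition percentages (protein, fat, moisture)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ("sample_id",) + TARGETS
        for col in required:
            if col not in df.columns:
                raise ParseError(f"quality table missing column '{col}'")
        df = df.loc[:, list(required)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ParseError(f"duplicate sample_id '{dup}' in quality table")
        for col in TARGETS:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(vals.index[vals.isna()][0])
                raise ParseError(f"non-numeric {col} value at row {row}")
            bad = (vals < 0) | (vals > 100)
            if bad.any():
                row = int(vals.index[bad][0])
                raise ParseError(
                    f"{col} value {vals[bad].iloc[0]!r} outside [0, 100] at row {row}"
                )
            df[col] = vals.astype(float)
        total = df[list(TARGETS)].sum(axis=1)
        if (total > 100 + 1e-9).any():
            row = int(total.index[total > 100 + 1e-9][0])
            raise ParseError(
                f"protein + fat + moisture exceeds 100% at row {row} "
                f"(sum {total.max():.3f})"
            )
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def values_for(self, parameter: str) -> np.ndarray:
        if parameter not in TARGETS:
            raise KeyError(f"unknown quality parameter '{parameter}'")
        return self.data[parameter].to_numpy(dtype=float)

    def select_samples(self, ids: Sequence[str]) -> "QualityTable":
        df = self.data.set_index("sample_id").loc[[str(s) for s in ids]]
        return QualityTable(df.reset_index())

    def aligned_to(self, spectra: SpectraSet) -> "QualityTable":
        """Reorder to the spectra's sample order; error on mismatch."""
        return self.select_samples(spectra.sample_ids)
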