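"""Containers and CSV I/O for NIR spectra and reference chemistry.

A :class:`SpectraSet` holds an ``n_samples x n_wavelengths`` absorbance
matrix on a shared :class:`WavelengthGrid` (1100-2100 nm for the larval
instrument range).  A :class:`ReferenceTable` carries the wet-chemistry
reference values each spectrum is calibrated against: crude fat in
g/100 g fresh weight and the fatty-acid profile in relative % of total
fatty acids (dry-matter basis).

File formats are deliberately plain: wide CSV, one row per sample, the
header naming each wavelength in nm, comma separator, dot decimal, UTF-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "ReferenceTable",
    "SummaryStats",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_csv",
    "write_reference_csv",
    "average_replicates",
    "summarize_reference",
    "absorbance_from_reflectance",
    "SpectraError",
]

WAVELENGTH_MIN = 1100.0
WAVELENGTH_MAX = 2100.0

#: canonical fatty-acid keys (shorthand nomenclature used throughout)
FATTY_ACIDS = (
    "C12:0",
    "C14:0",
    "C16:0",
    "C16:1",
    "C18:0",
    "C18:1w9",
    "C18:2w6",
    "C18:3w3",
)


class SpectraError(ValueError):
    """Raised for malformed spectra/reference inputs."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelengths in nm.

    The instrument window is 1100-2100 nm; values outside it are
    rejected so downstream band bookkeeping cannot silently run off
    the measured range.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise SpectraError("wavelength grid needs at least two points")
        if not np.all(np.isfinite(vals)):
            raise SpectraError("non-finite wavelength")
        steps = np.diff(vals)
        if np.any(steps <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise SpectraError("wavelength spacing must be uniform")
        if vals[0] < WAVELENGTH_MIN - 1e-9 or vals[-1] > WAVELENGTH_MAX + 1e-9:
            raise SpectraError(
                f"wavelengths must lie within [{WAVELENGTH_MIN:.0f}, "
                f"{WAVELENGTH_MAX:.0f}] nm"
            )

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, atol=1e-9)
        )

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    @classmethod
    def default(cls, start: float = 1100.0, stop: float = 2100.0,
                step: float = 2.0) -> "WavelengthGrid":
        """Default 2 nm grid (501 points) used by the synthetic generator."""
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


@dataclass(frozen=True)
class SpectraSet:
    """Absorbance spectra for a set of identified samples."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise SpectraError("absorbance must be a 2-D matrix")
        object.__setattr__(self, "absorbance", a)
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        if len(ids) != a.shape[0]:
            raise SpectraError("sample_ids must match the number of rows")
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise SpectraError(f"duplicate sample id(s): {', '.join(dupes)}")
        if a.shape[1] != len(self.grid):
            raise SpectraError("row length must match the wavelength grid")
        if not np.all(np.isfinite(a)):
            raise SpectraError("absorbance contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.absorbance,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{w:g}" for w in self.grid.values],
        )

    def select(self, ids) -> "SpectraSet":
        """Row subset in the given id order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [pos[str(s)] for s in ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
        return SpectraSet(self.grid, self.absorbance[rows], tuple(str(s) for s in ids))

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.grid, matrix, self.sample_ids)


@dataclass(frozen=True)
class ReferenceTable:
    """Per-sample reference chemistry.

    fat          -- g/100 g fresh weight (Soxhlet reference values)
    fa_profile   -- relative % of total fatty acids, dry-matter basis;
                    one column per fatty-acid key, NaN = not detected
    extra        -- optional additional constituents (e.g. water, protein
                    proxies used by the synthetic generator), one column
                    per constituent
    """

    sample_ids: tuple[str, ...]
    fat: np.ndarray
    fa_profile: pd.DataFrame | None = None
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        fat = np.asarray(self.fat, dtype=float)
        object.__setattr__(self, "fat", fat)
        if len(set(ids)) != len(ids):
            raise SpectraError("duplicate sample id in reference table")
        if fat.shape != (len(ids),):
            raise SpectraError("fat must be one value per sample")
        if not np.all(np.isfinite(fat)) or np.any(fat < 0):
            raise SpectraError("fat values must be finite and non-negative")
        for name in ("fa_profile", "extra"):
            df = getattr(self, name)
            if df is not None:
                if list(df.index) != list(ids):
                    df = df.copy()
                    df.index = pd.Index(ids, name="sample_id")
                object.__setattr__(self, name, df)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def analyte(self, name: str) -> np.ndarray:
        """Reference vector for one analyte.

        ``fat`` comes from the fat column; fatty-acid keys and the class
        sums SFA/MUFA/PUFA come from the profile; anything else from
        ``extra``.
        """
        if name == "fat":
            return self.fat.copy()
        if self.fa_profile is not None:
            if name in self.fa_profile.columns:
                return self.fa_profile[name].to_numpy(dtype=float)
            if name in ("SFA", "MUFA", "PUFA"):
                from .composition import class_sums, profile_from_row

                vals = [
                    getattr(class_sums(profile_from_row(row)), name.lower())
                    for _, row in self.fa_profile.iterrows()
                ]
                return np.asarray(vals, dtype=float)
        if self.extra is not None and name in self.extra.columns:
            return self.extra[name].to_numpy(dtype=float)
        raise KeyError(f"unknown analyte {name!r}")

    def select(self, ids) -> "ReferenceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[str(s)] for s in ids]
        ids_t = tuple(str(s) for s in ids)
        return ReferenceTable(
            ids_t,
            self.fat[rows],
            None if self.fa_profile is None else self.fa_profile.iloc[rows],
            None if self.extra is None else self.extra.iloc[rows],
        )


@dataclass(frozen=True)
class SummaryStats:
    """Mean / min / max / SD summary (SD with the n-1 denominator)."""

    mean: float
    minimum: float
    maximum: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise SpectraError("mean must lie between minimum and maximum")
        if self.sd < 0:
            raise SpectraError("sd must be non-negative")

    def to_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "minimum": self.minimum,
            "maximum": self.maximum,
            "sd": self.sd,
        }


def summarize_reference(values) -> SummaryStats:
    """Descriptive summary of a reference vector (sample SD, n-1)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise SpectraError("need at least two values to summarise")
    if not np.all(np.isfinite(v)):
        raise SpectraError("non-finite value in summary input")
    return SummaryStats(
        mean=float(np.mean(v)),
        minimum=float(np.min(v)),
        maximum=float(np.max(v)),
        sd=float(np.std(v, ddof=1)),
    )


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide spectra CSV: first column sample id, header = nm values."""
    df = pd.read_csv(path, index_col=0)
    try:
        wavelengths = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise SpectraError(f"non-numeric wavelength header: {exc}") from None
    order = np.argsort(wavelengths)
    df = df.iloc[:, order]
    wavelengths = wavelengths[order]
    for col in df.columns:
        bad = df[col].apply(
            lambda x: not isinstance(x, (int, float, np.integer, np.floating))
        )
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise SpectraError(f"non-numeric absorbance at row {row!r}, column {col}")
    if df.isna().any().any():
        raise SpectraError("missing absorbance values are not accepted")
    return SpectraSet(
        WavelengthGrid(wavelengths),
        df.to_numpy(dtype=float),
        tuple(str(i) for i in df.index),
    )


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    spectra.to_frame().to_csv(path, float_format="%.12g")


def read_reference_csv(path) -> ReferenceTable:
    """Read reference chemistry: columns ``sample_id, fat[, FA keys, ...]``."""
    df = pd.read_csv(path, index_col=0)
    if "fat" not in df.columns:
        raise SpectraError("reference table requires a 'fat' column")
    fa_cols = [c for c in df.columns if c in FATTY_ACIDS]
    other = [c for c in df.columns if c not in fa_cols and c != "fat"]
    return ReferenceTable(
        tuple(str(i) for i in df.index),
        df["fat"].to_numpy(dtype=float),
        df[fa_cols] if fa_cols else None,
        df[other] if other else None,
    )


def write_reference_csv(ref: ReferenceTable, path) -> None:
    parts = [pd.Series(ref.fat, index=list(ref.sample_ids), name="fat")]
    if ref.fa_profile is not None:
        parts.append(ref.fa_profile)
    if ref.extra is not None:
        parts.append(ref.extra)
    out = pd.concat(parts, axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.12g")


def average_replicates(spectra: SpectraSet, groups: dict[str, str]) -> SpectraSet:
    """Average replicate spectra into one spectrum per sample.

    ``groups`` maps replicate id -> output sample id.  Each larval sample
    is scanned repeatedly (quintuplicate measurements, 50 scans in all)
    and the averaged spectrum is what enters calibration.
    """
    pos = {s: i for i, s in enumerate(spectra.sample_ids)}
    out_ids: list[str] = []
    members: dict[str, list[int]] = {}
    for rep, sample in groups.items():
        if rep not in pos:
            raise KeyError(f"unknown replicate id {rep!r}")
        if sample not in members:
            members[sample] = []
            out_ids.append(sample)
        members[sample].append(pos[rep])
    rows = np.vstack([
        spectra.absorbance[members[s]].mean(axis=0) for s in out_ids
    ])
    return SpectraSet(spectra.grid, rows, tuple(out_ids))


def absorbance_from_reflectance(reflectance: np.ndarray) -> np.ndarray:
    """Optional log10(1/R) converter for reflectance input.

    The pipeline itself assumes absorbance; this helper covers
    instruments that export reflectance.
    """
    r = np.asarray(reflectance, dtype=float)
    if np.any(r <= 0):
        raise SpectraError("reflectance must be strictly positive")
    return -np.log10(r)
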