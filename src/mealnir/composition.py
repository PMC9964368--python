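"""Fatty-acid profile arithmetic.

Profiles are relative percentages of total fatty acids (dry-matter
basis), obtained from GC-FID by normalising peak areas.  A fatty acid
absent from a chromatogram ("not detected") is modelled as absence from
the mapping and contributes zero to class sums.

The saturation classes:

    SFA  = C12:0 + C14:0 + C16:0 + C18:0
    MUFA = C16:1 + C18:1w9
    PUFA = C18:2w6 + C18:3w3

The classification map is data, not code, so longer-chain acids
(C20:5, C22:6, ...) can be registered without touching the logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FattyAcidProfile",
    "ClassSums",
    "FA_CLASSES",
    "peak_areas_to_percent",
    "class_sums",
    "validate_profile_consistency",
    "profile_from_row",
    "CompositionError",
]


class CompositionError(ValueError):
    pass


#: saturation class per fatty-acid key
FA_CLASSES: dict[str, str] = {
    "C12:0": "sfa",
    "C14:0": "sfa",
    "C16:0": "sfa",
    "C18:0": "sfa",
    "C16:1": "mufa",
    "C18:1w9": "mufa",
    "C18:2w6": "pufa",
    "C18:3w3": "pufa",
}

SUM_TOLERANCE = 0.5  # percentage points allowed above 100 for a profile


@dataclass(frozen=True)
class FattyAcidProfile:
    """Relative % of total fatty acids; absent key = not detected."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = dict(self.values)
        object.__setattr__(self, "values", vals)
        for k, v in vals.items():
            if not np.isfinite(v) or v < 0:
                raise CompositionError(f"invalid percentage for {k}: {v}")
        if sum(vals.values()) > 100.0 + SUM_TOLERANCE:
            raise CompositionError("profile percentages exceed 100%")

    def get(self, key: str) -> float:
        return float(self.values.get(key, 0.0))

    def total(self) -> float:
        return float(sum(self.values.values()))


@dataclass(frozen=True)
class ClassSums:
    sfa: float
    mufa: float
    pufa: float

    def __post_init__(self) -> None:
        for v in (self.sfa, self.mufa, self.pufa):
            if v < 0:
                raise CompositionError("class sums must be non-negative")
        if self.sfa + self.mufa + self.pufa > 100.0 + 1.0:
            raise CompositionError("class sums exceed 100%")


def peak_areas_to_percent(areas: Mapping[str, float]) -> FattyAcidProfile:
    """Normalise raw GC peak areas to relative percentages of total FA."""
    if any(a < 0 for a in areas.values()):
        bad = [k for k, a in areas.items() if a < 0]
        raise CompositionError(f"negative peak area for {', '.join(bad)}")
    total = float(sum(areas.values()))
    if total <= 0:
        raise CompositionError("all peak areas are zero")
    return FattyAcidProfile({k: 100.0 * a / total for k, a in areas.items()})


def class_sums(
    profile: FattyAcidProfile,
    classification: Mapping[str, str] | None = None,
) -> ClassSums:
    """Sum a profile into SFA/MUFA/PUFA classes."""
    cls = dict(FA_CLASSES)
    if classification:
        cls.update(classification)
    acc = {"sfa": 0.0, "mufa": 0.0, "pufa": 0.0}
    for key, value in profile.values.items():
        if key not in cls:
            raise CompositionError(f"no saturation class for {key!r}")
        acc[cls[key]] += value
    return ClassSums(**acc)


def validate_profile_consistency(
    profile: FattyAcidProfile,
    printed: "ClassSums | Mapping[str, float]",
    tol: float = 0.2,
    classification: Mapping[str, str] | None = None,
) -> list[str]:
    """QC check: compare recomputed class sums with printed ones.

    Returns a message per class whose recomputed sum deviates from the
    printed value by more than ``tol`` percentage points.  Published
    composition tables occasionally print sums inconsistent with their
    own components (a printed row may even total over 100%, which
    :class:`ClassSums` itself would reject), so ``printed`` may be a
    plain mapping with keys sfa/mufa/pufa.  This surfaces, not
    resolves, such rows.
    """
    if tol < 0:
        raise CompositionError("tolerance must be non-negative")
    computed = class_sums(profile, classification)
    if not isinstance(printed, ClassSums):
        printed = dict(printed)
    out = []
    for name in ("sfa", "mufa", "pufa"):
        got = getattr(computed, name)
        want = (
            getattr(printed, name)
            if isinstance(printed, ClassSums)
            else float(printed[name])
        )
        if abs(got - want) > tol + 1e-12:
            out.append(
                f"{name.upper()}: components sum to {got:.1f} but printed "
                f"value is {want:.1f} (|diff| = {abs(got - want):.1f})"
            )
    return out


def profile_from_row(row) -> FattyAcidProfile:
    """Build a profile from a pandas row / mapping, dropping NaNs (n.d.)."""
    vals = {}
    for k, v in dict(row).items():
        if k in FA_CLASSES and v == v and v is not None:  # NaN-safe
            vals[k] = float(v)
    return FattyAcidProfile(vals)
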