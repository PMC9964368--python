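"""Rearing bookkeeping and diet-formulation arithmetic.

Growth metrics for a rearing group over a feeding trial:

    LWGpL = (total end weight - total start weight) / survivors   [mg/larva]
    FCR   = feed consumed / weight gained                          [-]
    ECI   = weight gained / feed consumed * 100                    [%]
    SGR   = (ln(final mean weight) - ln(initial mean weight))
            / experimental days * 100                              [%/day]

FCR and ECI are exact reciprocals (ECI = 100/FCR), which doubles as a
consistency check on any record.

Diets are linear mixtures of a supplement substrate and a wheat-bran
base; each nutrient of the mixture is the mass-fraction-weighted mean of
the component nutrients.  ``solve_inclusion`` inverts that relation for
a target nutrient level, and ``solve_component_values`` recovers the two
component levels from two published mixtures of the same pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthRecord",
    "GrowthMetrics",
    "DietFormulation",
    "lwgpl",
    "fcr",
    "eci",
    "sgr",
    "survival_rate",
    "growth_metrics",
    "mix_nutrients",
    "solve_inclusion",
    "solve_component_values",
    "HusbandryError",
]

NUTRIENTS = ("moisture", "protein", "fat", "carbohydrate", "fiber", "ash")


class HusbandryError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthRecord:
    """Group-level rearing record. Weights in mg; duration in days."""

    group: str
    n_start: int
    n_dead: int
    start_weight: float   # total, mg
    end_weight: float     # total, mg
    feed_consumed: float  # mg (offered - residual - frass by default)
    days: float

    def __post_init__(self) -> None:
        if self.n_start <= 0:
            raise HusbandryError("n_start must be positive")
        if not (0 <= self.n_dead <= self.n_start):
            raise HusbandryError("n_dead must be within [0, n_start]")
        if self.start_weight < 0 or self.end_weight < 0 or self.feed_consumed < 0:
            raise HusbandryError("weights must be non-negative")
        if self.days <= 0:
            raise HusbandryError("days must be positive")

    @property
    def survivors(self) -> int:
        return self.n_start - self.n_dead

    @property
    def weight_gain(self) -> float:
        return self.end_weight - self.start_weight


@dataclass(frozen=True)
class GrowthMetrics:
    lwgpl: float      # mg per larva
    fcr: float        # dimensionless
    eci: float        # %
    sgr: float        # % per day
    survival: float   # %

    def to_dict(self) -> dict[str, float]:
        return {
            "LWGpL": self.lwgpl,
            "FCR": self.fcr,
            "ECI": self.eci,
            "SGR": self.sgr,
            "survival": self.survival,
        }


def lwgpl(record: GrowthRecord) -> float:
    """Larval weight gain per surviving larva, mg."""
    if record.survivors <= 0:
        raise HusbandryError("no surviving larvae")
    return record.weight_gain / record.survivors


def fcr(record: GrowthRecord) -> float:
    """Feed conversion ratio: feed consumed over weight gained."""
    if record.weight_gain <= 0:
        raise HusbandryError("weight gain must be positive for FCR")
    return record.feed_consumed / record.weight_gain


def eci(record: GrowthRecord) -> float:
    """Efficiency of conversion of ingested food, % (= 100/FCR)."""
    if record.feed_consumed <= 0:
        raise HusbandryError("feed consumed must be positive for ECI")
    return record.weight_gain / record.feed_consumed * 100.0


def sgr(record: GrowthRecord) -> float:
    """Specific growth rate, % per day, from mean per-larva weights."""
    if record.start_weight <= 0 or record.end_weight <= 0:
        raise HusbandryError("weights must be positive for SGR")
    if record.survivors <= 0:
        raise HusbandryError("no surviving larvae")
    w0 = record.start_weight / record.n_start
    w1 = record.end_weight / record.survivors
    return (math.log(w1) - math.log(w0)) / record.days * 100.0


def survival_rate(record: GrowthRecord) -> float:
    return 100.0 * record.survivors / record.n_start


def growth_metrics(record: GrowthRecord) -> GrowthMetrics:
    return GrowthMetrics(
        lwgpl=lwgpl(record),
        fcr=fcr(record),
        eci=eci(record),
        sgr=sgr(record),
        survival=survival_rate(record),
    )


@dataclass(frozen=True)
class DietFormulation:
    """Mass fractions and nutrient vectors (% FW) of diet components."""

    components: tuple[tuple[str, float, dict[str, float]], ...]

    def __post_init__(self) -> None:
        fracs = [f for _, f, _ in self.components]
        if any(f < 0 for f in fracs):
            raise HusbandryError("mass fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise HusbandryError("mass fractions must sum to 1")
        for name, _, nut in self.components:
            if sum(nut.values()) > 100.0 + 0.5:
                raise HusbandryError(f"nutrients of {name!r} exceed 100%")


def mix_nutrients(formulation: DietFormulation) -> dict[str, float]:
    """Fraction-weighted nutrient vector of a mixture."""
    keys: list[str] = []
    for _, _, nut in formulation.components:
        for k in nut:
            if k not in keys:
                keys.append(k)
    return {
        k: sum(f * nut.get(k, 0.0) for _, f, nut in formulation.components)
        for k in keys
    }


def solve_inclusion(target: float, substrate_value: float, base_value: float) -> float:
    """Substrate mass fraction p with ``p*substrate + (1-p)*base = target``."""
    if substrate_value == base_value:
        raise HusbandryError("component values must differ")
    lo, hi = sorted((substrate_value, base_value))
    if not (lo <= target <= hi):
        raise HusbandryError(
            f"target {target} outside component range [{lo}, {hi}]"
        )
    return (target - base_value) / (substrate_value - base_value)


def solve_component_values(
    mix1: tuple[float, float], mix2: tuple[float, float]
) -> tuple[float, float]:
    """Recover (substrate_value, base_value) from two (fraction, target) pairs."""
    (f1, t1), (f2, t2) = mix1, mix2
    A = np.array([[f1, 1.0 - f1], [f2, 1.0 - f2]], dtype=float)
    if abs(np.linalg.det(A)) < 1e-12:
        raise HusbandryError("mixtures do not determine the components")
    s, b = np.linalg.solve(A, np.array([t1, t2], dtype=float))
    return float(s), float(b)
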