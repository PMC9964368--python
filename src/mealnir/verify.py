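"""Arithmetic self-checks over the bundled case-study tables.

Three families of identities connect the published numbers:

* RPD = validation-set SD / RMSEP for every best model;
* each group's SFA/MUFA/PUFA sum equals the sum of its components
  (a handful of printed sums are internally inconsistent and are
  reported as known discrepancies rather than failures);
* the diet-formulation linear model: recovering coconut-flour and
  wheat-bran fat contents from the CF10/CF15 mixtures and inverting for
  a 20% fat target reproduces the CF20 inclusion level.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import casestudy
from .composition import ClassSums, class_sums, profile_from_row, validate_profile_consistency
from .husbandry import solve_component_values, solve_inclusion
from .metrics import rpd

__all__ = ["Check", "verify_tables", "cf20_inclusion_from_mixing"]


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    expected: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance + 1e-9


def rpd_checks(tol: float = 0.03) -> list[Check]:
    out = []
    for analyte, row in casestudy.BEST_MODELS.items():
        rmsep, printed_rpd = row[5], row[6]
        out.append(
            Check(
                name=f"rpd:{analyte}",
                computed=rpd(casestudy.VALIDATION_SD[analyte], rmsep),
                expected=printed_rpd,
                tolerance=tol,
            )
        )
    return out


def class_sum_checks(tol: float = 0.2) -> list[Check]:
    """Recomputed vs printed class sums, skipping documented discrepancies."""
    out = []
    known = set(casestudy.KNOWN_SUM_DISCREPANCIES)
    for group, printed in casestudy.PRINTED_CLASS_SUMS.items():
        prof = profile_from_row(casestudy.FA_PROFILES[group])
        sums = class_sums(prof)
        for cls, want in zip(("sfa", "mufa", "pufa"), printed):
            if (group, cls) in known:
                continue
            out.append(
                Check(
                    name=f"classsum:{group}:{cls}",
                    computed=getattr(sums, cls),
                    expected=want,
                    tolerance=tol,
                )
            )
    return out


def known_discrepancies() -> list[str]:
    """The printed sums the QC check flags as internally inconsistent."""
    msgs = []
    for group, cls in casestudy.KNOWN_SUM_DISCREPANCIES:
        printed = dict(
            zip(("sfa", "mufa", "pufa"), casestudy.PRINTED_CLASS_SUMS[group])
        )
        prof = profile_from_row(casestudy.FA_PROFILES[group])
        flags = validate_profile_consistency(prof, printed, tol=0.2)
        msgs += [f"{group}: {m}" for m in flags if m.lower().startswith(cls)]
    return msgs


def cf20_inclusion_from_mixing() -> float:
    """Coconut-flour inclusion (%) needed for a 20.0% fat diet.

    Solves the substrate/base fat contents from the CF10 and CF15
    mixtures, then inverts the linear mixing model for the 20% target.
    """
    f10 = casestudy.DIET_INCLUSION["CF10"] / 100.0
    f15 = casestudy.DIET_INCLUSION["CF15"] / 100.0
    t10 = casestudy.DIET_NUTRIENTS["CF10"]["fat"]
    t15 = casestudy.DIET_NUTRIENTS["CF15"]["fat"]
    substrate_fat, base_fat = solve_component_values((f10, t10), (f15, t15))
    return 100.0 * solve_inclusion(20.0, substrate_fat, base_fat)


def mixing_checks(tol: float = 0.3) -> list[Check]:
    return [
        Check(
            name="inclusion:CF20",
            computed=cf20_inclusion_from_mixing(),
            expected=casestudy.DIET_INCLUSION["CF20"],
            tolerance=tol,
        )
    ]


def verify_tables() -> list[Check]:
    """All in-table arithmetic identities."""
    return rpd_checks() + class_sum_checks() + mixing_checks()
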