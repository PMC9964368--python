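"""Spectral pretreatments: MSC, detrend, mean centering, SG derivatives.

All stateful transforms (MSC reference spectrum, centering means) are
fitted on the calibration set only and replayed unchanged on validation
or prediction spectra, so no information leaks across the split.

Step labels follow the chemometrics shorthand used in calibration
reports: ``none``, ``msc``, ``detrend``, ``mc``, ``d1``, ``d2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet, SpectraError

__all__ = [
    "PretreatmentSpec",
    "FittedPretreatment",
    "msc_fit_apply",
    "msc_transform",
    "detrend",
    "mean_center_fit",
    "mean_center_transform",
    "sg_derivative",
    "apply_pipeline",
    "PRETREATMENT_PRESETS",
]

# window/polyorder defaults for SG derivatives; the derivative method is
# standard but smoothing parameters are a free choice, echoed in reports.
SG_WINDOW_DEFAULT = 11
SG_POLYORDER_DEFAULT = 2
DETREND_ORDER_DEFAULT = 2


@dataclass(frozen=True)
class Step:
    """One pretreatment step."""

    kind: str  # none | msc | detrend | mean_center | derivative
    order: int = 0  # detrend polynomial order, or derivative order (1|2)
    window: int = SG_WINDOW_DEFAULT
    polyorder: int = SG_POLYORDER_DEFAULT


@dataclass(frozen=True)
class PretreatmentSpec:
    """Ordered list of pretreatment steps with a report label."""

    steps: tuple[Step, ...]
    label: str

    def __post_init__(self) -> None:
        n_mc = sum(1 for s in self.steps if s.kind == "mean_center")
        if n_mc > 1:
            raise SpectraError("at most one mean-centering step is allowed")
        for s in self.steps:
            if s.kind == "derivative":
                if s.order not in (1, 2):
                    raise SpectraError("derivative order must be 1 or 2")
                if s.window % 2 == 0 or s.window <= s.polyorder:
                    raise SpectraError("SG window must be odd and > polyorder")
                if s.order > s.polyorder:
                    raise SpectraError("derivative order must be <= polyorder")
            elif s.kind == "detrend":
                if s.order < 0:
                    raise SpectraError("detrend order must be >= 0")
            elif s.kind not in ("none", "msc", "mean_center"):
                raise SpectraError(f"unknown pretreatment step {s.kind!r}")

    @classmethod
    def parse(cls, label: str) -> "PretreatmentSpec":
        """Parse a label like ``none``, ``mc``, ``d2`` or ``msc+detrend``."""
        steps = []
        for tok in label.lower().split("+"):
            tok = tok.strip()
            if tok == "none":
                steps.append(Step("none"))
            elif tok == "msc":
                steps.append(Step("msc"))
            elif tok == "detrend":
                steps.append(Step("detrend", order=DETREND_ORDER_DEFAULT))
            elif tok == "mc":
                steps.append(Step("mean_center"))
            elif tok in ("d1", "1d"):
                steps.append(Step("derivative", order=1))
            elif tok in ("d2", "2d"):
                steps.append(Step("derivative", order=2))
            else:
                raise SpectraError(f"unknown pretreatment token {tok!r}")
        return cls(tuple(steps), label)


#: the candidate pretreatments screened per analyte in reports
PRETREATMENT_PRESETS = ("none", "msc", "mc", "d1", "d2")


@dataclass
class FittedPretreatment:
    """Calibration-fitted state for a pretreatment pipeline."""

    spec: PretreatmentSpec
    msc_reference: np.ndarray | None = None
    msc_coefficients: np.ndarray | None = None  # (n, 2): additive a, slope b
    column_means: np.ndarray | None = None

    def transform(self, new: SpectraSet) -> SpectraSet:
        """Replay the fitted pipeline on new spectra."""
        out = new
        for step in self.spec.steps:
            if step.kind == "none":
                continue
            if step.kind == "msc":
                out = msc_transform(out, self)
            elif step.kind == "detrend":
                out = detrend(out, step.order)
            elif step.kind == "mean_center":
                out = mean_center_transform(out, self.column_means)
            elif step.kind == "derivative":
                out = sg_derivative(out, step.window, step.polyorder, step.order)
        return out


def _msc_correct(matrix: np.ndarray, reference: np.ndarray):
    """Regress each row on the reference; return corrected rows and (a, b)."""
    ref = reference - reference.mean()
    denom = float(ref @ ref)
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    b = centered @ ref / denom
    a = matrix.mean(axis=1) - b * reference.mean()
    small = np.abs(b) < 1e-12
    if np.any(small):
        raise SpectraError(
            f"degenerate spectrum (flat against reference) at row(s) "
            f"{np.flatnonzero(small).tolist()}"
        )
    corrected = (matrix - a[:, None]) / b[:, None]
    return corrected, np.column_stack([a, b])


def msc_fit_apply(cal: SpectraSet, fitted: FittedPretreatment | None = None):
    """Multiplicative scatter correction fitted on the calibration set.

    The reference is the mean calibration spectrum; each spectrum s is
    modelled as ``s = a + b * reference`` by least squares and corrected
    to ``(s - a) / b``.
    """
    if cal.n_samples < 2:
        raise SpectraError("MSC needs at least two calibration spectra")
    reference = cal.absorbance.mean(axis=0)
    corrected, coef = _msc_correct(cal.absorbance, reference)
    if fitted is None:
        fitted = FittedPretreatment(PretreatmentSpec.parse("msc"))
    fitted.msc_reference = reference
    fitted.msc_coefficients = coef
    return cal.with_absorbance(corrected), fitted


def msc_transform(new: SpectraSet, fitted: FittedPretreatment) -> SpectraSet:
    """Correct new spectra against the stored calibration reference."""
    if fitted.msc_reference is None:
        raise SpectraError("MSC has not been fitted")
    if fitted.msc_reference.size != len(new.grid):
        raise SpectraError("wavelength grid does not match the fitted MSC")
    corrected, _ = _msc_correct(new.absorbance, fitted.msc_reference)
    return new.with_absorbance(corrected)


def detrend(spectra: SpectraSet, order: int = DETREND_ORDER_DEFAULT) -> SpectraSet:
    """Remove a least-squares polynomial baseline from each spectrum.

    Stateless: the polynomial is fitted per spectrum in wavelength, so
    the same call applies to calibration and validation data.
    """
    n_wl = len(spectra.grid)
    if order < 0:
        raise SpectraError("detrend order must be >= 0")
    if order >= n_wl:
        raise SpectraError("detrend order must be below the number of wavelengths")
    # scaled wavelength for conditioning
    x = (spectra.grid.values - spectra.grid.values.mean()) / (
        np.ptp(spectra.grid.values) / 2.0
    )
    basis = np.vander(x, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, spectra.absorbance.T, rcond=None)
    return spectra.with_absorbance(spectra.absorbance - (basis @ coef).T)


def mean_center_fit(cal: SpectraSet, fitted: FittedPretreatment | None = None):
    """Centre calibration columns; store the means for later replay."""
    if cal.n_samples < 2:
        raise SpectraError("mean centering needs at least two spectra")
    means = cal.absorbance.mean(axis=0)
    if fitted is None:
        fitted = FittedPretreatment(PretreatmentSpec.parse("mc"))
    fitted.column_means = means
    return cal.with_absorbance(cal.absorbance - means), fitted


def mean_center_transform(new: SpectraSet, column_means: np.ndarray) -> SpectraSet:
    if column_means is None:
        raise SpectraError("mean centering has not been fitted")
    if column_means.size != len(new.grid):
        raise SpectraError("wavelength grid does not match the fitted centering")
    return new.with_absorbance(new.absorbance - column_means)


def sg_derivative(
    spectra: SpectraSet,
    window: int = SG_WINDOW_DEFAULT,
    polyorder: int = SG_POLYORDER_DEFAULT,
    deriv: int = 1,
) -> SpectraSet:
    """Savitzky-Golay derivative with respect to wavelength (per nm).

    The grid step is passed through so first derivatives are in AU/nm
    and second derivatives in AU/nm^2.  Edge points use the polynomial
    fitted on the truncated window (scipy's ``interp`` edge mode).
    """
    if window % 2 == 0:
        raise SpectraError("SG window must be odd")
    if polyorder >= window:
        raise SpectraError("SG polyorder must be below the window length")
    if deriv not in (1, 2) or deriv > polyorder:
        raise SpectraError("derivative order must be 1 or 2 and <= polyorder")
    out = savgol_filter(
        spectra.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv,
        delta=spectra.grid.step,
        axis=1,
        mode="interp",
    )
    return spectra.with_absorbance(out)


def apply_pipeline(
    spec: PretreatmentSpec,
    cal: SpectraSet,
    others: list[SpectraSet] | None = None,
):
    """Fit a pretreatment pipeline on ``cal`` and replay it on ``others``.

    Returns ``(transformed_cal, transformed_others, fitted)``.  Steps run
    in the listed order; stateful steps fit on the calibration set only.
    """
    others = list(others or [])
    for o in others:
        if o.grid != cal.grid:
            raise SpectraError("wavelength grids must match across sets")
    fitted = FittedPretreatment(spec)
    out_cal = cal
    out_others = others
    for step in spec.steps:
        if step.kind == "none":
            continue
        if step.kind == "msc":
            out_cal, fitted = msc_fit_apply(out_cal, fitted)
            out_others = [msc_transform(o, fitted) for o in out_others]
        elif step.kind == "detrend":
            out_cal = detrend(out_cal, step.order)
            out_others = [detrend(o, step.order) for o in out_others]
        elif step.kind == "mean_center":
            out_cal, fitted = mean_center_fit(out_cal, fitted)
            out_others = [
                mean_center_transform(o, fitted.column_means) for o in out_others
            ]
        elif step.kind == "derivative":
            out_cal = sg_derivative(out_cal, step.window, step.polyorder, step.order)
            out_others = [
                sg_derivative(o, step.window, step.polyorder, step.order)
                for o in out_others
            ]
    return out_cal, out_others, fitted
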