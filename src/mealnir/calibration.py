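"""High-level calibration workflow: model and results objects.

:class:`NIRCalibration` is built from a calibration spectra/reference
pair for one analyte and a pretreatment recipe; ``fit()`` returns a
:class:`CalibrationResults` carrying the fitted pretreatment state, the
PLS model, training diagnostics, and ``predict`` / ``validate`` /
``summary`` methods.  :func:`run_calibration` screens several
pretreatments per analyte and assembles the report tables.

Example
-------
>>> from mealnir import simulate, calibration
>>> cal_s, cal_r, val_s, val_r = simulate.make_case_study(seed=1)
>>> model = calibration.NIRCalibration(cal_s, cal_r, analyte="fat",
...                                    pretreatment="msc+mc")
>>> res = model.fit()
>>> metrics = res.validate(val_s, val_r)
>>> round(metrics.r2_p, 3) >= 0.95
True
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as mt
from .pls import LV_CAP_DEFAULT, CVResult, PLSModel, cross_validate, fit_pls1, predict
from .preprocess import (
    PRETREATMENT_PRESETS,
    FittedPretreatment,
    PretreatmentSpec,
    apply_pipeline,
)
from .spectra import ReferenceTable, SpectraSet, SpectraError

__all__ = [
    "NIRCalibration",
    "CalibrationResults",
    "ValidationMetrics",
    "run_calibration",
    "ANALYTES",
]

logger = logging.getLogger("mealnir")

#: the analytes screened by default: fat, the eight fatty acids, and the
#: saturation-class sums
ANALYTES = (
    "fat",
    "C12:0", "C14:0", "C16:0", "C16:1", "C18:0",
    "C18:1w9", "C18:2w6", "C18:3w3",
    "SFA", "MUFA", "PUFA",
)


def grid_hash(grid) -> str:
    h = hashlib.sha256(np.round(grid.values, 6).tobytes())
    return h.hexdigest()[:16]


def _align(spectra: SpectraSet, ref: ReferenceTable):
    """Join by sample id; order follows the spectra."""
    missing = [s for s in spectra.sample_ids if s not in ref.sample_ids]
    if missing:
        raise SpectraError(
            f"reference values missing for sample(s): {', '.join(missing[:5])}"
        )
    return ref.select(spectra.sample_ids)


@dataclass(frozen=True)
class ValidationMetrics:
    analyte: str
    r2_p: float
    rmsep: float
    rpd: float
    n: int


class NIRCalibration:
    """PLS calibration of one analyte from NIR spectra.

    Parameters
    ----------
    spectra, reference : calibration set, joined by sample id.
    analyte : name of the response ("fat", a fatty-acid key, or
        SFA/MUFA/PUFA).
    pretreatment : label such as ``none``, ``msc``, ``mc``, ``d1``,
        ``d2`` or combinations like ``msc+mc``; or a
        :class:`PretreatmentSpec`.
    lv_cap : complexity limit for cross-validated selection.
    """

    def __init__(
        self,
        spectra: SpectraSet,
        reference: ReferenceTable,
        analyte: str = "fat",
        pretreatment: str | PretreatmentSpec = "mc",
        lv_cap: int = LV_CAP_DEFAULT,
        cv_scheme: str = "venetian",
        cv_splits: int = 10,
    ) -> None:
        self.spectra = spectra
        self.reference = _align(spectra, reference)
        self.analyte = analyte
        self.y = self.reference.analyte(analyte)
        if float(np.std(self.y)) <= 0:
            raise mt.MetricsError(f"zero-variance reference for {analyte!r}")
        if isinstance(pretreatment, str):
            pretreatment = PretreatmentSpec.parse(pretreatment)
        self.pretreatment = pretreatment
        self.lv_cap = lv_cap
        self.cv_scheme = cv_scheme
        self.cv_splits = cv_splits

    def fit(self, n_lv: int | None = None) -> "CalibrationResults":
        """Fit pretreatment + PLS; select LVs by RMSECV unless forced."""
        cal_t, _, fitted = apply_pipeline(self.pretreatment, self.spectra, [])
        X = cal_t.absorbance
        cv = None
        if n_lv is None:
            cv = cross_validate(
                X,
                self.y,
                max_lv=self.lv_cap,
                scheme=self.cv_scheme,
                n_splits=self.cv_splits,
                cap=self.lv_cap,
            )
            n_lv = cv.chosen_n_lv
            logger.info(
                "analyte=%s pretreatment=%s cv=%s chosen_lv=%d",
                self.analyte, self.pretreatment.label, cv.scheme, n_lv,
            )
        model = fit_pls1(
            X,
            self.y,
            n_lv,
            metadata={
                "analyte": self.analyte,
                "pretreatment": self.pretreatment.label,
                "grid_hash": grid_hash(self.spectra.grid),
            },
        )
        return CalibrationResults(self, fitted, model, cv)


class CalibrationResults:
    """Fitted calibration: estimates, diagnostics, prediction."""

    def __init__(
        self,
        model: NIRCalibration,
        fitted_pretreatment: FittedPretreatment,
        pls: PLSModel,
        cv: CVResult | None,
    ) -> None:
        self.model = model
        self.fitted_pretreatment = fitted_pretreatment
        self.pls = pls
        self.cv = cv
        self.fitted_values = self.predict(model.spectra)
        self.r2_c = mt.r_squared(model.y, self.fitted_values)
        self.rmsec = mt.rmse(model.y, self.fitted_values)

    @property
    def n_lv(self) -> int:
        return self.pls.n_lv

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        """Pretreat new spectra with the stored state and predict."""
        if spectra.grid != self.model.spectra.grid:
            raise SpectraError("wavelength grid does not match the calibration")
        transformed = self.fitted_pretreatment.transform(spectra)
        return predict(self.pls, transformed.absorbance)

    def validate(
        self, spectra: SpectraSet, reference: ReferenceTable
    ) -> ValidationMetrics:
        """Evaluate on an independent validation set."""
        ref = _align(spectra, reference)
        y_val = ref.analyte(self.model.analyte)
        pred = self.predict(spectra)
        rmsep = mt.rmse(y_val, pred)
        return ValidationMetrics(
            analyte=self.model.analyte,
            r2_p=mt.r_squared(y_val, pred),
            rmsep=rmsep,
            rpd=mt.rpd(float(np.std(y_val, ddof=1)), rmsep),
            n=len(y_val),
        )

    def summary(self) -> str:
        lines = [
            f"NIR PLS calibration: {self.model.analyte}",
            f"  pretreatment        {self.model.pretreatment.label}",
            f"  latent variables    {self.n_lv}",
            f"  n (calibration)     {self.model.spectra.n_samples}",
            f"  R2_C                {self.r2_c:.3f}",
            f"  RMSEC               {self.rmsec:.3f}",
            "  explained y-var     "
            + " ".join(f"{v:.3f}" for v in self.pls.explained_y_variance),
        ]
        if self.cv is not None:
            lines.append(
                "  RMSECV per LV       "
                + " ".join(f"{v:.3f}" for v in self.cv.rmsecv)
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        doc = json.loads(self.pls.to_json())
        doc["pretreatment"] = {
            "label": self.model.pretreatment.label,
            "msc_reference": (
                None
                if self.fitted_pretreatment.msc_reference is None
                else self.fitted_pretreatment.msc_reference.tolist()
            ),
            "column_means": (
                None
                if self.fitted_pretreatment.column_means is None
                else self.fitted_pretreatment.column_means.tolist()
            ),
        }
        doc["grid"] = self.model.spectra.grid.values.tolist()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)


def load_results(path):
    """Load a saved calibration for prediction-only use.

    Returns ``(pls_model, fitted_pretreatment, grid_values)``.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    pls = PLSModel.from_json(json.dumps(doc))
    spec = PretreatmentSpec.parse(doc["pretreatment"]["label"])
    fitted = FittedPretreatment(spec)
    if doc["pretreatment"]["msc_reference"] is not None:
        fitted.msc_reference = np.asarray(doc["pretreatment"]["msc_reference"])
    if doc["pretreatment"]["column_means"] is not None:
        fitted.column_means = np.asarray(doc["pretreatment"]["column_means"])
    return pls, fitted, np.asarray(doc["grid"], dtype=float)


def run_calibration(
    cal_spectra: SpectraSet,
    cal_ref: ReferenceTable,
    val_spectra: SpectraSet,
    val_ref: ReferenceTable,
    analytes=("fat",),
    pretreatments=PRETREATMENT_PRESETS,
    lv_cap: int = LV_CAP_DEFAULT,
    n_lv: int | None = None,
) -> dict[str, mt.CalibrationReport]:
    """Screen pretreatments per analyte and build report tables.

    For each analyte x pretreatment: fit on the calibration set
    (cross-validated LV choice unless ``n_lv`` forces a count), evaluate
    on the validation set, and mark the best row (highest RPD, ties to
    lower RMSEP then fewer LVs).
    """
    val_ref_aligned = _align(val_spectra, val_ref)
    reports: dict[str, mt.CalibrationReport] = {}
    for analyte in analytes:
        evaluations = {}
        for label in pretreatments:
            res = NIRCalibration(
                cal_spectra, cal_ref, analyte=analyte, pretreatment=label,
                lv_cap=lv_cap,
            ).fit(n_lv=n_lv)
            evaluations[label] = {
                "n_lv": res.n_lv,
                "pred_cal": res.fitted_values,
                "pred_val": res.predict(val_spectra),
            }
        reports[analyte] = mt.build_report(
            analyte,
            evaluations,
            y_cal=NIRCalibration(
                cal_spectra, cal_ref, analyte=analyte
            ).y,
            y_val=val_ref_aligned.analyte(analyte),
            fat_val=None if analyte == "fat" else val_ref_aligned.analyte("fat"),
        )
    return reports


def reports_to_frame(reports: dict[str, mt.CalibrationReport],
                     round_display: bool = False) -> pd.DataFrame:
    return pd.concat(
        [r.to_frame(round_display) for r in reports.values()],
        ignore_index=True,
    )
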