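"""Calibration/validation statistics and best-model selection.

The figures of merit follow standard chemometrics usage:

* RMSEC / RMSEP -- root mean square error on the calibration /
  validation set, in the analyte's own units.
* R2_C / R2_P   -- coefficient of determination, 1 - SSE/SST with SST
  about the mean of the observed values in the same set.
* RPD           -- ratio of performance to deviation: the validation-set
  reference SD (n-1 denominator) divided by RMSEP.  RPD >= 3 is the
  conventional bar for routine-analysis quality.
* R2_F          -- squared Pearson correlation between a fatty acid's
  relative concentration and the total fat content; a diagnostic of
  whether a fatty-acid model could merely be riding on fat bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "rmse",
    "r_squared",
    "rpd",
    "r2_fat_correlation",
    "ReportRow",
    "CalibrationReport",
    "build_report",
    "select_best_model",
    "MetricsError",
]


class MetricsError(ValueError):
    pass


def rmse(y_true, y_pred) -> float:
    t = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if t.size == 0:
        raise MetricsError("empty input to rmse")
    if t.size != p.size:
        raise MetricsError("length mismatch in rmse")
    return float(np.sqrt(np.mean((t - p) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """1 - SSE/SST; can be negative for models worse than the mean."""
    t = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if t.size != p.size or t.size == 0:
        raise MetricsError("length mismatch in r_squared")
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst <= 0:
        raise MetricsError("zero-variance reference values")
    sse = float(np.sum((t - p) ** 2))
    return 1.0 - sse / sst


def rpd(reference_sd: float, rmsep: float) -> float:
    """Ratio of performance to deviation (validation SD / RMSEP)."""
    if rmsep <= 0:
        raise MetricsError("RMSEP must be positive for RPD")
    if reference_sd < 0:
        raise MetricsError("reference SD must be non-negative")
    return float(reference_sd) / float(rmsep)


def r2_fat_correlation(fa_values, fat_values) -> float:
    """Squared correlation of a fatty acid's relative % with total fat."""
    a = np.asarray(fa_values, dtype=float).ravel()
    b = np.asarray(fat_values, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise MetricsError("need >= 3 paired values")
    va, vb = np.var(a), np.var(b)
    if va <= 0 or vb <= 0:
        warnings.warn(
            "zero variance in fatty-acid/fat correlation; reporting 0",
            stacklevel=2,
        )
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ReportRow:
    """One pretreatment's performance for one analyte."""

    pretreatment: str
    n_lv: int
    r2_c: float
    rmsec: float
    r2_p: float
    rmsep: float
    rpd: float
    r2_f: float | None = None
    chosen: bool = False

    def __post_init__(self) -> None:
        if self.rmsec < 0 or self.rmsep < 0:
            raise MetricsError("RMSE values must be non-negative")
        if self.rpd <= 0:
            raise MetricsError("RPD must be positive")


@dataclass(frozen=True)
class CalibrationReport:
    """Per-pretreatment performance table for one analyte."""

    analyte: str
    rows: tuple[ReportRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MetricsError("report has no rows")
        if sum(1 for r in self.rows if r.chosen) != 1:
            raise MetricsError("exactly one row must be chosen")

    @property
    def chosen(self) -> ReportRow:
        return next(r for r in self.rows if r.chosen)

    def to_frame(self, round_display: bool = False) -> pd.DataFrame:
        cols = {
            "analyte": [self.analyte] * len(self.rows),
            "pretreatment": [r.pretreatment for r in self.rows],
            "n_lv": [r.n_lv for r in self.rows],
            "r2_c": [r.r2_c for r in self.rows],
            "rmsec": [r.rmsec for r in self.rows],
            "r2_p": [r.r2_p for r in self.rows],
            "rmsep": [r.rmsep for r in self.rows],
            "rpd": [r.rpd for r in self.rows],
            "r2_f": [r.r2_f for r in self.rows],
            "chosen": [r.chosen for r in self.rows],
        }
        df = pd.DataFrame(cols)
        if round_display:
            for c in ("r2_c", "rmsec", "r2_p", "rmsep"):
                df[c] = df[c].round(3)
            df["rpd"] = df["rpd"].round(2)
            df["r2_f"] = df["r2_f"].astype(float).round(3)
        return df


def build_report(
    analyte: str,
    evaluations: dict,
    y_cal,
    y_val,
    fat_val=None,
) -> CalibrationReport:
    """Assemble a report from per-pretreatment predictions.

    ``evaluations`` maps pretreatment label -> dict with keys ``n_lv``,
    ``pred_cal`` and ``pred_val``.  RPD uses the validation reference SD;
    R2_F is attached for fatty-acid analytes when validation fat values
    are supplied.
    """
    if not evaluations:
        raise MetricsError("no pretreatments evaluated")
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if y_val.size < 2:
        raise MetricsError("validation references are missing or too few")
    val_sd = float(np.std(y_val, ddof=1))
    r2f = None
    if fat_val is not None and analyte != "fat":
        r2f = r2_fat_correlation(y_val, fat_val)
    rows = []
    for label, ev in evaluations.items():
        rmsep_v = rmse(y_val, ev["pred_val"])
        rpd_v = np.inf if rmsep_v == 0 else rpd(val_sd, rmsep_v)
        rows.append(
            ReportRow(
                pretreatment=label,
                n_lv=int(ev["n_lv"]),
                r2_c=r_squared(y_cal, ev["pred_cal"]),
                rmsec=rmse(y_cal, ev["pred_cal"]),
                r2_p=r_squared(y_val, ev["pred_val"]),
                rmsep=rmsep_v,
                rpd=rpd_v,
                r2_f=r2f,
            )
        )
    best = select_best_model(rows)
    rows = [
        ReportRow(**{**r.__dict__, "chosen": r is best}) for r in rows
    ]
    return CalibrationReport(analyte=analyte, rows=tuple(rows))


def select_best_model(rows) -> ReportRow:
    """Highest RPD; ties broken by lower RMSEP, then fewer latent variables."""
    rows = list(rows)
    if not rows:
        raise MetricsError("no rows to select from")
    return min(rows, key=lambda r: (-r.rpd, r.rmsep, r.n_lv))
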