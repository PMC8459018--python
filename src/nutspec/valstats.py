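"""Calibration/validation error statistics and NIR reporting conventions.

Definitions follow long-standing NIR calibration practice:

* SEC  = sqrt(SSE / (n - f - 1)) on the calibration set (f = PLS factors),
* SECV = sqrt(mean squared cross-validated residual),
* RSQ  = 1 - SSE/SST on the calibration set,
* bias = mean validation residual; SEP = sqrt(sum((e - bias)^2) / (n - 1))
  (bias-corrected; the uncorrected RMSEP is reported alongside),
* Est. Min / Est. Max = calibration mean -/+ 3 SD — the stated range of
  applicability of a model,
* percent errors = 100 * error / midpoint of (Est. Min, Est. Max).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np


def sec(residuals: np.ndarray, n_factors: int) -> float:
    """Standard error of calibration with n - f - 1 degrees of freedom."""
    e = np.asarray(residuals, dtype=np.float64).ravel()
    if e.size <= n_factors + 1:
        raise ValueError("SEC needs n > f + 1")
    return float(np.sqrt((e**2).sum() / (e.size - n_factors - 1)))


def secv(cv_residuals: np.ndarray) -> float:
    """Standard error of cross-validation (root mean square CV residual)."""
    e = np.asarray(cv_residuals, dtype=np.float64).ravel()
    return float(np.sqrt((e**2).mean()))


def rsq(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Calibration coefficient of determination."""
    y = np.asarray(y, dtype=np.float64).ravel()
    e = y - np.asarray(y_hat, dtype=np.float64).ravel()
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("SST is zero; RSQ undefined")
    return float(1.0 - (e**2).sum() / sst)


def sep(y_val: np.ndarray, y_hat_val: np.ndarray) -> tuple[float, float, float]:
    """External-validation errors: (SEP, bias, RMSEP).

    SEP is the bias-corrected standard error of prediction (n - 1
    denominator); RMSEP is the plain root mean square error.
    """
    y = np.asarray(y_val, dtype=np.float64).ravel()
    e = y - np.asarray(y_hat_val, dtype=np.float64).ravel()
    if e.size < 3:
        raise ValueError("external validation needs at least 3 samples")
    bias = float(e.mean())
    sep_val = float(np.sqrt(((e - bias) ** 2).sum() / (e.size - 1)))
    rmsep = float(np.sqrt((e**2).mean()))
    return sep_val, bias, rmsep


def estimated_range(y_cal: np.ndarray) -> tuple[float, float]:
    """Model applicability range: calibration mean -/+ 3 SD (ddof=1)."""
    y = np.asarray(y_cal, dtype=np.float64).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 calibration values")
    sd = float(y.std(ddof=1))
    mean = float(y.mean())
    return mean - 3.0 * sd, mean + 3.0 * sd


def percent_error(err: float, est_min: float, est_max: float) -> float:
    """Error as a percentage of the mean of the applicability range."""
    mid = (est_min + est_max) / 2.0
    if mid == 0:
        raise ValueError("range midpoint is zero; percent error undefined")
    return 100.0 * err / mid


@dataclass
class ValidationReport:
    """One analyte's row of a model-performance table."""

    analyte: str
    pretreatment: str
    t_outliers: int
    n_factors: int
    n_cal: int
    n_val: int
    est_min: float
    sd_cal: float
    est_max: float
    sec: float
    rsq: float
    secv: float
    sep: float
    bias: float
    rmsep: float
    secv_pct: float
    sep_pct: float

    def to_row(self) -> dict:
        row = asdict(self)
        # percentages rounded half-even to 3 decimals in emitted tables
        for key in ("secv_pct", "sep_pct"):
            row[key] = float(np.round(row[key], 3))
        return row


def build_report(
    model,
    y_cal_kept: np.ndarray,
    y_val: np.ndarray,
    y_hat_val: np.ndarray,
) -> ValidationReport:
    """Assemble the per-analyte report row from a fitted model + validation."""
    y_cal_kept = np.asarray(y_cal_kept, dtype=np.float64).ravel()
    est_min, est_max = estimated_range(y_cal_kept)
    sep_val, bias, rmsep = sep(y_val, y_hat_val)
    return ValidationReport(
        analyte=model.analyte,
        pretreatment=model.pretreatment.code.serialize(),
        t_outliers=len(model.removed_outliers),
        n_factors=model.n_factors,
        n_cal=model.n_train,
        n_val=int(np.asarray(y_val).size),
        est_min=est_min,
        sd_cal=float(y_cal_kept.std(ddof=1)),
        est_max=est_max,
        sec=model.sec,
        rsq=model.rsq,
        secv=model.secv,
        sep=sep_val,
        bias=bias,
        rmsep=rmsep,
        secv_pct=percent_error(model.secv, est_min, est_max),
        sep_pct=percent_error(sep_val, est_min, est_max),
    )


def write_reports(reports: list[ValidationReport], csv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Emit report rows as delimited text (and optionally JSON)."""
    import pandas as pd

    rows = [r.to_row() for r in reports]
    frame = pd.DataFrame(rows)
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=1))
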