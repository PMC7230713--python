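"""Model evaluation: calibration metrics, grading, and the model matrix.

Metric conventions follow standard Vis-NIR calibration reporting:

* ``R^2`` in percent, ``RMSE`` in percent scaling rate;
* ``SD`` is the sample standard deviation of the *predicted* scaling rates
  expressed on the fractional scale (percent / 100), with ``SE = SD/sqrt(n)``;
* ``RPD = (100 * SD_pred) / RMSEP`` — the prediction-set SD over the
  prediction RMSE, both on the percent scale.

Grading: prediction accuracy is inaccurate / good / excellent for
``R_P^2`` below 82 %, in [82, 90] %, above 90 %; predictive usability is
unusable / usable / excellent for RPD below 1.5, in [1.5, 2], above 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SpectralDataset
from .plsr import fit_plsr, predict, select_latent_variables, split_dataset
from .preprocessing import PRETREATMENTS, apply_pretreatment
from .selection import (
    WavelengthSubset,
    autopeak_select,
    rc_select,
    spa_select,
    synchronous_spectrum,
)

__all__ = [
    "EvaluationReport",
    "ModelGrade",
    "ModelMatrixConfig",
    "compute_metrics",
    "rpd_from_sd_rmsep",
    "grade_model",
    "run_model_matrix",
    "reports_to_frame",
    "select_optimal_model",
]

#: Wavelength-set labels in report order: full wavelengths then the three
#: characteristic-wavelength selectors.
WAVELENGTH_SETS = ("FW", "SPA", "RC", "2D-COS")

REPORT_COLUMNS = [
    "model",
    "n_vars",
    "R2C_pct",
    "RMSEC_pct",
    "SDC",
    "SEC",
    "R2P_pct",
    "RMSEP_pct",
    "RPD",
    "SDP",
    "SEP",
    "fit_grade",
    "rpd_grade",
]


@dataclass
class EvaluationReport:
    """One row of the evaluation matrix for a named model."""

    model_name: str
    n_variables: int
    r2_cal: float
    rmsec: float
    sd_cal: float
    se_cal: float
    r2_pred: float
    rmsep: float
    rpd: float
    sd_pred: float
    se_pred: float
    note: str = ""

    @property
    def sd_cal_pct(self) -> float:
        """Calibration predicted-value SD on the percent scale."""
        return self.sd_cal * 100.0

    @property
    def sd_pred_pct(self) -> float:
        """Prediction predicted-value SD on the percent scale."""
        return self.sd_pred * 100.0

    @property
    def stability(self) -> float:
        """|RMSEC - RMSEP| in percent — small values mean a stable model."""
        return abs(self.rmsec - self.rmsep)


@dataclass(frozen=True)
class ModelGrade:
    """Pure-function grades of prediction accuracy and usability."""

    fit_grade: str
    rpd_grade: str


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, set_label: str = "") -> dict:
    """R^2 (%), RMSE (%), and predicted-value SD/SE (fractional scale).

    ``set_label`` is carried through for report assembly (``calibration`` or
    ``prediction``); it does not change the arithmetic.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length vectors (n >= 2)")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("zero response variance: R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    sd = float(np.std(y_pred, ddof=1)) / 100.0
    n = y_true.size
    return {
        "set": set_label,
        "n": n,
        "r2": 100.0 * (1.0 - ss_res / ss_tot),
        "rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
        "sd": sd,
        "se": sd / math.sqrt(n),
    }


def rpd_from_sd_rmsep(sd_pred: float, rmsep: float) -> float:
    """RPD from a fractional-scale prediction SD and a percent-scale RMSEP."""
    if rmsep <= 0:
        raise ValueError("RMSEP must be positive")
    return 100.0 * sd_pred / rmsep


def grade_model(report: EvaluationReport) -> ModelGrade:
    """Grade a report by its prediction R^2 and RPD thresholds."""
    r2, rpd = report.r2_pred, report.rpd
    if r2 < 82.0:
        fit = "inaccurate"
    elif r2 <= 90.0:
        fit = "good"
    else:
        fit = "excellent"
    if rpd < 1.5:
        usability = "unusable"
    elif rpd <= 2.0:
        usability = "usable"
    else:
        usability = "excellent"
    return ModelGrade(fit_grade=fit, rpd_grade=usability)


@dataclass(frozen=True)
class ModelMatrixConfig:
    """Knobs of the 4-pretreatment x 4-wavelength-set evaluation matrix."""

    n_cal: int = 60
    n_pred: int = 40
    split_strategy: str = "rank"
    seed: int = 0
    spa_k_min: int = 1
    spa_k_max: int | None = None  # None -> spa_select's sample-size-based cap
    rc_n_keep: int = 8
    cos_max_peaks: int = 8
    max_lv: int = 20
    cv_folds: int = 10


def _evaluate_subset(
    Xc: np.ndarray,
    yc: np.ndarray,
    Xp: np.ndarray,
    yp: np.ndarray,
    name: str,
    cfg: ModelMatrixConfig,
) -> EvaluationReport:
    cap = min(cfg.max_lv, Xc.shape[0] - 1, Xc.shape[1])
    n_lv = select_latent_variables(
        Xc, yc, max_lv=cap, folds=min(cfg.cv_folds, Xc.shape[0]), seed=cfg.seed
    )
    model = fit_plsr(Xc, yc, n_lv)
    cal = compute_metrics(yc, predict(model, Xc), "calibration")
    pred = compute_metrics(yp, predict(model, Xp), "prediction")
    return EvaluationReport(
        model_name=name,
        n_variables=Xc.shape[1],
        r2_cal=cal["r2"],
        rmsec=cal["rmse"],
        sd_cal=cal["sd"],
        se_cal=cal["se"],
        r2_pred=pred["r2"],
        rmsep=pred["rmse"],
        rpd=rpd_from_sd_rmsep(pred["sd"], pred["rmse"]),
        sd_pred=pred["sd"],
        se_pred=pred["se"],
    )


def _flagged_report(name: str, note: str) -> EvaluationReport:
    nan = float("nan")
    return EvaluationReport(
        model_name=name,
        n_variables=0,
        r2_cal=nan,
        rmsec=nan,
        sd_cal=nan,
        se_cal=nan,
        r2_pred=nan,
        rmsep=nan,
        rpd=nan,
        sd_pred=nan,
        se_pred=nan,
        note=note,
    )


def run_model_matrix(
    ds: SpectralDataset, config: ModelMatrixConfig | None = None
) -> list[EvaluationReport]:
    """Evaluate all 16 pretreatment x wavelength-set PLSR models of a region.

    For each pretreatment (SG, FD, MSC, SNV) the whole-region dataset is
    pretreated (MSC's reference is the whole-dataset mean), split into
    calibration/prediction sets, and modelled on full wavelengths and on the
    SPA, RC and 2D-COS characteristic-wavelength subsets (all selected on
    the calibration set only). Deterministic for a fixed config seed. A
    selector returning an empty subset flags that row instead of failing.
    """
    cfg = config or ModelMatrixConfig()
    split = split_dataset(
        ds, cfg.n_cal, cfg.n_pred, strategy=cfg.split_strategy, seed=cfg.seed
    )

    pretreated = {name: apply_pretreatment(ds, name) for name in PRETREATMENTS}
    reports: list[EvaluationReport] = []
    for selector in WAVELENGTH_SETS:
        for pre in PRETREATMENTS:
            ds_p = pretreated[pre]
            cal = ds_p.select_samples(split.calibration_indices)
            prd = ds_p.select_samples(split.prediction_indices)
            name = f"{pre}-PLSR" if selector == "FW" else f"{pre}-{selector}-PLSR"
            try:
                if selector == "FW":
                    subset = None
                elif selector == "SPA":
                    subset = spa_select(cal, cfg.spa_k_min, cfg.spa_k_max)
                elif selector == "RC":
                    subset = rc_select(cal, n_keep=cfg.rc_n_keep)
                else:
                    subset = autopeak_select(
                        synchronous_spectrum(cal), max_peaks=cfg.cos_max_peaks
                    )
                if subset is not None and len(subset) == 0:
                    reports.append(_flagged_report(name, "empty wavelength subset"))
                    continue
                Xc, Xp = cal.spectra, prd.spectra
                if subset is not None:
                    Xc, Xp = Xc[:, subset.indices], Xp[:, subset.indices]
                reports.append(
                    _evaluate_subset(Xc, cal.responses, Xp, prd.responses, name, cfg)
                )
            except ValueError as exc:
                reports.append(_flagged_report(name, str(exc)))
    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Tabulate reports with the standard column layout and grades."""
    rows = []
    for r in reports:
        if r.note:
            grade = ModelGrade("flagged", "flagged")
        else:
            grade = grade_model(r)
        rows.append(
            {
                "model": r.model_name,
                "n_vars": r.n_variables,
                "R2C_pct": r.r2_cal,
                "RMSEC_pct": r.rmsec,
                "SDC": r.sd_cal,
                "SEC": r.se_cal,
                "R2P_pct": r.r2_pred,
                "RMSEP_pct": r.rmsep,
                "RPD": r.rpd,
                "SDP": r.sd_pred,
                "SEP": r.se_pred,
                "fit_grade": grade.fit_grade,
                "rpd_grade": grade.rpd_grade,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def select_optimal_model(reports: list[EvaluationReport]) -> str:
    """Pick the recommended characteristic-wavelength model.

    Among CW-based reports (full-wavelength rows are excluded — their 352
    variables defeat the point of selection), ranks by prediction R^2,
    breaking ties by stability |RMSEC - RMSEP| (smaller wins) and then RPD.
    """
    cw = [
        r
        for r in reports
        if not r.note
        and any(tag in r.model_name for tag in ("-SPA-", "-RC-", "-2D-COS-"))
    ]
    if not cw:
        raise ValueError("no characteristic-wavelength reports to choose from")
    best = min(cw, key=lambda r: (-r.r2_pred, r.stability, -r.rpd))
    return best.model_name
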