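"""Calibration of noninvasive pressure surrogates against invasive CVP.

Unit conversions (cmH2O -> mmHg with C = 0.7356, hydrostatic offset
HO = 10*sin(theta) under the fixed 10-cm atrium-to-neck assumption, JVP
height conversion JVP = h*sin(theta)*C), ordinary-least-squares fits of
invasive CVP on collapse force and/or hydrostatic offset, evaluation of a
previously trained fixed-coefficient model, and agreement metrics
(squared Pearson correlation, mean absolute error, sample SD of the signed
error).  The hydrostatic offset always enters regressions and the trained
model in mmHg (converted by C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .study_data import StudyTable, SubjectRecord

__all__ = [
    "CMH2O_TO_MMHG",
    "HO_DISTANCE_CM",
    "TRAINED_MODEL_COEFFS",
    "RegressionFit",
    "hydrostatic_offset",
    "cmh2o_to_mmhg",
    "jvp_to_mmhg",
    "fit_linear",
    "predict",
    "apply_trained_model",
    "agreement_metrics",
]

#: Pressure conversion constant, mmHg per cmH2O.
CMH2O_TO_MMHG = 0.7356

#: Assumed distance (cm) from the middle of the right atrium to the
#: measurement site on the neck; HO = 10*sin(theta) cmH2O.
HO_DISTANCE_CM = 10.0

#: Fixed coefficients of the previously trained linear model:
#: CVP = 0.42*CF + 0.054 + HO_mmHg.
TRAINED_MODEL_COEFFS = {"cf_slope": 0.42, "intercept": 0.054}

#: Predictor extractors; HO is supplied to fits in mmHg.
_PREDICTORS = {
    "CF": lambda r: r.collapse_force,
    "HO_mmHg": lambda r: None if r.ho_cmh2o is None else cmh2o_to_mmhg(r.ho_cmh2o),
    "JVP": lambda r: r.jvp_mmhg,
}


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of invasive CVP on one or more noninvasive predictors."""

    predictor_names: tuple[str, ...]
    coefficients: Mapping[str, float]
    intercept: float
    p_values: Mapping[str, float]
    intercept_p_value: float
    r_squared: float
    mae: float
    sd_error: float
    residuals: np.ndarray
    n: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.r_squared <= 1.0 + 1e-12
        assert self.mae >= 0
        assert len(self.residuals) == self.n


def hydrostatic_offset(theta_deg: float) -> float:
    """Hydrostatic offset HO (cmH2O) at inclination ``theta_deg``:
    10*sin(theta) for the fixed 10-cm column."""
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError(f"inclination angle must be in [0, 90] deg, got {theta_deg}")
    return HO_DISTANCE_CM * math.sin(math.radians(theta_deg))


def cmh2o_to_mmhg(p_cmh2o: float) -> float:
    return p_cmh2o * CMH2O_TO_MMHG


def jvp_to_mmhg(h_cm: float, theta_deg: float) -> float:
    """Convert a jugular pulsation head height measured along the neck
    (cm at inclination ``theta_deg``) to pressure: h*sin(theta)*C."""
    if h_cm < 0:
        raise ValueError("height must be >= 0")
    return h_cm * math.sin(math.radians(theta_deg)) * CMH2O_TO_MMHG


def _design(table: StudyTable, predictors: Sequence[str]) -> tuple[np.ndarray, np.ndarray, int]:
    unknown = set(predictors) - set(_PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictor(s) {sorted(unknown)}; choose from {sorted(_PREDICTORS)}")
    rows, y = [], []
    for r in table:
        vals = [_PREDICTORS[p](r) for p in predictors]
        if any(v is None for v in vals):
            continue
        rows.append(vals)
        y.append(r.avg_invasive_cvp)
    return np.asarray(rows, float), np.asarray(y, float), len(y)


def fit_linear(table: StudyTable, predictors: Sequence[str] = ("CF",)) -> RegressionFit:
    """OLS of average invasive CVP on the chosen predictors, with intercept.

    Predictors: ``CF`` (collapse force, N), ``HO_mmHg`` (hydrostatic offset
    converted to mmHg), ``JVP`` (mmHg).  Records missing any chosen
    predictor are dropped.  Requires at least p+1 complete records — the
    minimum that determines the coefficients; with exactly p+1 the fit
    interpolates (r²=1) and the coefficient t-tests are undefined.
    """
    predictors = tuple(predictors)
    X, y, n = _design(table, predictors)
    if n < len(predictors) + 1:
        raise ValueError(
            f"insufficient records: {n} complete rows for {len(predictors)} predictor(s)"
        )
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("singular design matrix (collinear predictors)")
    res = sm.OLS(y, Xc).fit()
    resid = np.asarray(res.resid)
    return RegressionFit(
        predictor_names=predictors,
        coefficients={p: float(res.params[i + 1]) for i, p in enumerate(predictors)},
        intercept=float(res.params[0]),
        p_values={p: float(res.pvalues[i + 1]) for i, p in enumerate(predictors)},
        intercept_p_value=float(res.pvalues[0]),
        r_squared=float(res.rsquared),
        mae=float(np.mean(np.abs(resid))),
        sd_error=float(np.std(resid, ddof=1)),
        residuals=resid,
        n=n,
    )


def predict(fit: RegressionFit, record: SubjectRecord) -> float:
    """Evaluate a fit on one record (mmHg)."""
    total = fit.intercept
    for p in fit.predictor_names:
        v = _PREDICTORS[p](record)
        if v is None:
            raise ValueError(f"record {record.subject_id} missing predictor {p}")
        total += fit.coefficients[p] * v
    return float(total)


def predict_from_cf(fit: RegressionFit, cf_newtons: float, record: SubjectRecord) -> float:
    """Evaluate a fit with the record's CF replaced by ``cf_newtons`` —
    used to push collapse-force uncertainty bounds through a calibration."""
    total = fit.intercept
    for p in fit.predictor_names:
        v = cf_newtons if p == "CF" else _PREDICTORS[p](record)
        if v is None:
            raise ValueError(f"record {record.subject_id} missing predictor {p}")
        total += fit.coefficients[p] * v
    return float(total)


def apply_trained_model(record: SubjectRecord) -> float:
    """CVP estimate (mmHg) from the fixed, previously trained linear model:
    0.42*CF + 0.054 + HO (HO converted to mmHg).

    The published coefficients are rounded, so agreement with the study's
    printed per-subject values is expected only to ~a few hundredths of a
    mmHg.
    """
    if record.collapse_force is None or record.ho_cmh2o is None:
        raise ValueError(f"record {record.subject_id} missing CF or HO")
    c = TRAINED_MODEL_COEFFS
    return (
        c["cf_slope"] * record.collapse_force
        + c["intercept"]
        + cmh2o_to_mmhg(record.ho_cmh2o)
    )


def apply_trained_model_cf(cf_newtons: float, record: SubjectRecord) -> float:
    """Trained model evaluated at an alternate CF (for uncertainty bounds)."""
    if record.ho_cmh2o is None:
        raise ValueError(f"record {record.subject_id} missing HO")
    c = TRAINED_MODEL_COEFFS
    return c["cf_slope"] * cf_newtons + c["intercept"] + cmh2o_to_mmhg(record.ho_cmh2o)


def agreement_metrics(pred: Sequence[float], truth: Sequence[float]) -> dict[str, float]:
    """Agreement between predictions and invasive truth: squared Pearson
    correlation, mean absolute error, and sample SD (n-1) of the signed
    error about its mean."""
    p = np.asarray(pred, float)
    t = np.asarray(truth, float)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if len(p) < 2:
        raise ValueError("need at least 2 pairs")
    if np.allclose(p, p[0]) and not np.allclose(t, t[0]):
        raise ValueError("zero variance in predictions")
    if np.allclose(t, t[0]) and not np.allclose(p, p[0]):
        raise ValueError("zero variance in truth")
    err = p - t
    if np.allclose(p, p[0]) and np.allclose(t, t[0]):
        r2 = 1.0
    else:
        r2 = float(np.corrcoef(p, t)[0, 1] ** 2)
    return {
        "r_squared": r2,
        "mae": float(np.mean(np.abs(err))),
        "sd_error": float(np.std(err, ddof=1)),
    }
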