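"""Uncertainty intervals per estimation method and the overlap-accuracy
statistic comparing noninvasive CVP estimates to the invasive scalar.

Four uncertainty sources are quantified: the collapse-force interval
propagated through the calibration, the hydrostatic term (±0.5 mmHg for
angle imprecision and population variation in atrium-to-neck distance),
the invasive measurement's respiratory variation (±2 SD of the filtered
waveform), and the bedside JVP reading (±0.5 mmHg from repeatability and
whole-number rounding).  A method "hits" a subject when the invasive scalar
falls inside the method's interval; the overlap accuracy is the hit
fraction with method-specific eligibility rules (external-jugular subjects
are excluded from force-based methods, and JVP attempts that could not be
read at the patient's inclination count as forced misses).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import calibration
from .calibration import RegressionFit
from .collapse_force import CollapseEstimate
from .signal_processing import TimeSeries, respiratory_sd
from .study_data import JvpStatus, StudyTable, SubjectRecord

__all__ = [
    "HYDROSTATIC_UNCERT_MMHG",
    "JVP_UNCERT_MMHG",
    "IntervalSource",
    "Method",
    "UncertaintyInterval",
    "OverlapReport",
    "method_interval",
    "invasive_interval",
    "overlap_accuracy",
    "plot_overlap_accuracies",
]

#: Hydrostatic-pressure uncertainty after conversion to mmHg.
HYDROSTATIC_UNCERT_MMHG = 0.5

#: JVP reading uncertainty, each direction.
JVP_UNCERT_MMHG = 0.5


class IntervalSource(enum.Enum):
    CF_WAVEFORM = "cf_waveform"
    HYDROSTATIC = "hydrostatic"
    JVP_MEASUREMENT = "jvp_measurement"
    INVASIVE_RESPIRATORY = "invasive_respiratory"
    COMBINED = "combined"


class Method(enum.Enum):
    CF = "CF"
    CF_HO = "CF_HO"
    JVP = "JVP"
    TRAINED_MODEL = "TrainedModel"


@dataclass(frozen=True)
class UncertaintyInterval:
    center: float
    lo: float
    hi: float
    source: IntervalSource

    def __post_init__(self) -> None:
        if not (self.lo <= self.center <= self.hi):
            raise ValueError("interval must satisfy lo <= center <= hi")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class OverlapReport:
    method: Method
    n_eligible: int
    n_hits: int
    n_forced_misses: int

    @property
    def accuracy(self) -> float:
        return self.n_hits / (self.n_eligible + self.n_forced_misses)

    def to_dict(self) -> dict:
        return {
            "method": self.method.value,
            "n_eligible": self.n_eligible,
            "n_hits": self.n_hits,
            "n_forced_misses": self.n_forced_misses,
            "accuracy": self.accuracy,
        }


def method_interval(
    method: Method,
    record: SubjectRecord,
    collapse: CollapseEstimate | None = None,
    fit: RegressionFit | None = None,
) -> UncertaintyInterval:
    """Uncertainty interval of one method's CVP estimate for one subject.

    Force-based methods push the collapse-force bounds through the
    calibration (the interval lives in predicted-CVP units) and widen by
    ±0.5 mmHg for the hydrostatic term whenever HO is part of the model.
    JVP uses the fixed ±0.5 mmHg reading uncertainty about the measured
    value.
    """
    if method is Method.JVP:
        if record.jvp_status is not JvpStatus.MEASURED or record.jvp_mmhg is None:
            raise ValueError(f"subject {record.subject_id}: no measured JVP")
        j = record.jvp_mmhg
        return UncertaintyInterval(j, j - JVP_UNCERT_MMHG, j + JVP_UNCERT_MMHG,
                                   IntervalSource.JVP_MEASUREMENT)

    if collapse is None or collapse.cf_lo is None or collapse.cf_hi is None:
        raise ValueError(f"{method.value} interval requires a collapse estimate with bounds")

    if method is Method.TRAINED_MODEL:
        center = calibration.apply_trained_model(record)
        lo = calibration.apply_trained_model_cf(collapse.cf_lo, record)
        hi = calibration.apply_trained_model_cf(collapse.cf_hi, record)
        has_ho = True
        source = IntervalSource.COMBINED
    else:
        if fit is None:
            raise ValueError(f"{method.value} interval requires a calibration fit")
        center = calibration.predict(fit, record)
        lo = calibration.predict_from_cf(fit, collapse.cf_lo, record)
        hi = calibration.predict_from_cf(fit, collapse.cf_hi, record)
        has_ho = "HO_mmHg" in fit.predictor_names
        source = IntervalSource.COMBINED if has_ho else IntervalSource.CF_WAVEFORM
    lo, hi = min(lo, hi), max(lo, hi)
    if has_ho:
        lo -= HYDROSTATIC_UNCERT_MMHG
        hi += HYDROSTATIC_UNCERT_MMHG
    return UncertaintyInterval(center, min(lo, center), max(hi, center), source)


def invasive_interval(waveform: TimeSeries) -> UncertaintyInterval:
    """Invasive CVP uncertainty: mean ± 2 SD of the respiratory component
    of the waveform (cardiac content filtered out first)."""
    if waveform.duration < 10.0:
        raise ValueError("invasive waveform must cover at least 10 s")
    m = waveform.mean()
    half = 2.0 * respiratory_sd(waveform)
    return UncertaintyInterval(m, m - half, m + half, IntervalSource.INVASIVE_RESPIRATORY)


def overlap_accuracy(
    method: Method,
    table: StudyTable,
    intervals: Mapping[int, UncertaintyInterval],
) -> OverlapReport:
    """Fraction of eligible subjects whose interval contains the invasive
    scalar CVP (point-in-interval; invasive uncertainty deliberately not
    used).

    Eligibility: force-based methods exclude subjects measured on an
    external jugular (thrombosed IJV); JVP scores measured subjects
    normally, counts attempted-but-unmeasurable subjects as forced misses,
    and excludes not-attempted subjects entirely.
    """
    n_eligible = n_hits = n_forced = 0
    for rec in table:
        if method is Method.JVP:
            if rec.jvp_status is JvpStatus.NOT_ATTEMPTED:
                continue
            if rec.jvp_status is JvpStatus.ATTEMPTED_UNMEASURABLE:
                n_forced += 1
                continue
        else:
            if rec.vein.is_external:
                continue
        n_eligible += 1
        iv = intervals.get(rec.subject_id)
        if iv is None:
            raise ValueError(f"missing interval for eligible subject {rec.subject_id}")
        if iv.contains(rec.avg_invasive_cvp):
            n_hits += 1
    if n_eligible + n_forced == 0:
        raise ValueError("no eligible subjects")
    return OverlapReport(method, n_eligible, n_hits, n_forced)


def plot_overlap_accuracies(reports: list[OverlapReport], path: str) -> None:
    """Bar chart of per-method overlap accuracies (matplotlib, Agg)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    names = [r.method.value for r in reports]
    accs = [r.accuracy for r in reports]
    ax.bar(names, accs, color="steelblue")
    ax.set_ylabel("overlap accuracy")
    ax.set_ylim(0, 1)
    for x, a in zip(names, accs):
        ax.text(x, a + 0.02, f"{a:.3f}", ha="center", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
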