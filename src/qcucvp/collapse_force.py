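"""Collapse-force extraction from a synchronized QCU capture.

The collapse force (CF) is the minimum probe force that fully occludes the
vein's short-axis cross-section; occlusion is declared when the segmented
area first dips below 0.5 mm² during the force ramp.  Because the venous
pressure waveform beats and breathes under the probe, the area near collapse
swings with the cardiac and respiratory cycles; the CF uncertainty interval
is built by fitting lower and upper per-cardiac-cycle area envelopes over
the near-collapse ramp window as linear functions of force and extrapolating
each envelope to the occlusion threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synthetic_data import OCCLUSION_THRESHOLD_MM2, QCUCapture

__all__ = ["CollapseEstimate", "find_collapse_force", "cf_uncertainty"]


@dataclass(frozen=True)
class CollapseEstimate:
    cf: float                 # N
    collapse_time: float      # s, on the force channel's clock
    threshold_mm2: float = OCCLUSION_THRESHOLD_MM2
    cf_lo: float | None = None
    cf_hi: float | None = None

    def __post_init__(self) -> None:
        if not self.cf > 0:
            raise ValueError("cf must be > 0")
        if self.cf_lo is not None and self.cf_hi is not None:
            if not (self.cf_lo <= self.cf_hi):
                raise ValueError("cf_lo must not exceed cf_hi")


def find_collapse_force(
    capture: QCUCapture, threshold_mm2: float = OCCLUSION_THRESHOLD_MM2
) -> CollapseEstimate:
    """CF = force at the first ramp sample whose IJV area is below the
    occlusion threshold (first-crossing rule; ties break to earlier time).

    Raises ValueError("pre-collapsed") when the vein is already occluded at
    the start of the ramp, and ValueError("no collapse detected") when the
    ramp never occludes it.
    """
    sl = capture.phase_slice("ramp")
    area = capture.ijv_area.values[sl]
    force = capture.force.values[sl]
    if area[0] < threshold_mm2:
        raise ValueError("pre-collapsed: vein occluded at ramp start")
    below = np.flatnonzero(area < threshold_mm2)
    if below.size == 0:
        raise ValueError("no collapse detected: ramp never occludes the vein")
    i = int(below[0])
    t = capture.force.t0 + (sl.start + i) * capture.force.dt
    return CollapseEstimate(cf=float(force[i]), collapse_time=float(t),
                            threshold_mm2=threshold_mm2)


def _cycle_envelopes(
    force: np.ndarray, area: np.ndarray, samples_per_cycle: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-cardiac-cycle minima and maxima of area with the force at which
    each extremum occurs.  Blocks are anchored at the collapse end of the
    window so the last cycle abuts the detected collapse."""
    n_cyc = len(area) // samples_per_cycle
    f_lo, a_lo, f_hi, a_hi = [], [], [], []
    end = len(area)
    for c in range(n_cyc):
        blk = slice(end - (c + 1) * samples_per_cycle, end - c * samples_per_cycle)
        i_min = int(np.argmin(area[blk])) + blk.start
        i_max = int(np.argmax(area[blk])) + blk.start
        a_lo.append(area[i_min]); f_lo.append(force[i_min])
        a_hi.append(area[i_max]); f_hi.append(force[i_max])
    return np.array(f_lo), np.array(a_lo), np.array(f_hi), np.array(a_hi)


def cf_uncertainty(
    capture: QCUCapture,
    estimate: CollapseEstimate,
    window_s: float = 5.0,
    cardiac_period_s: float = 1.0,
) -> CollapseEstimate:
    """Fill ``cf_lo``/``cf_hi`` by linear extrapolation of the near-collapse
    area envelopes.

    Over the ``window_s`` of ramp preceding the detected collapse (the
    default covers at least one respiratory period at typical rates), the
    per-cardiac-cycle minima and maxima of the area are regressed on force
    in log-area coordinates — near collapse a compressed vein's area falls
    off exponentially with applied force, so its log is the coordinate in
    which the envelope trend is straight and a linear extrapolation to the
    occlusion threshold is meaningful.  The forces where the two envelope
    lines cross the threshold bound the feasible CF: the lower (minimum)
    envelope reaches it at the least force, the upper (maximum) envelope at
    the most, and the spread directly reflects the cardiac plus respiratory
    pressure swing expressed in force units.  Bounds are clipped to
    [0, max ramp force]; a crossing outside the ramp is reported with a
    warning.
    """
    sl = capture.phase_slice("ramp")
    dt = capture.force.dt
    area = capture.ijv_area.values[sl]
    force = capture.force.values[sl]
    t_ramp0 = capture.force.t0 + sl.start * dt
    i_col = int(round((estimate.collapse_time - t_ramp0) / dt))
    i_start = max(i_col - int(round(window_s / dt)), 0)
    w_force = force[i_start:i_col]
    w_area = area[i_start:i_col]
    spc = int(round(cardiac_period_s / dt))
    if len(w_area) < 2 * spc:
        raise ValueError(
            f"window too short to form envelopes: {len(w_area) * dt:.2f} s "
            f"covers fewer than two cardiac cycles"
        )
    f_lo, a_lo, f_hi, a_hi = _cycle_envelopes(w_force, w_area, spc)

    max_force = float(np.max(force))
    thr = estimate.threshold_mm2
    log_thr = np.log(thr)
    ref_max = float(np.max(w_area))

    # common compression slope d(log area)/d(force), fitted on the samples
    # just before collapse, where the vein is unambiguously compressed and
    # the log-area trend is straight
    tail = slice(max(len(w_area) - 2 * spc, 0), None)
    log_a = np.log(np.maximum(w_area[tail], 1e-6))
    slope = 0.0
    if np.ptp(w_force[tail]) > 1e-12:
        slope = float(np.polyfit(w_force[tail], log_a, 1)[0])
    if slope >= 0:  # no compression trend: envelopes carry no force information
        lo = hi = estimate.cf
    else:
        # envelope lines share the compression slope; their intercepts come
        # from the extreme per-cycle residuals among compressed envelope
        # points (distended points near the relaxed-area ceiling are
        # uninformative), so the spread measures the full cardiac plus
        # respiratory swing near collapse
        def intercept(f: np.ndarray, a: np.ndarray, pick) -> float:
            for cap_frac in (0.6, 0.8, 1.01):
                keep = a < cap_frac * ref_max
                if keep.sum() >= 1:
                    f, a = f[keep], a[keep]
                    break
            return float(pick(np.log(np.maximum(a, 1e-6)) - slope * f))

        b_lo = intercept(f_lo, a_lo, np.min)
        b_hi = intercept(f_hi, a_hi, np.max)
        lo = (log_thr - b_lo) / slope
        hi = (log_thr - b_hi) / slope
    if lo < 0 or hi > max_force:
        warnings.warn(
            "envelope crossing outside the ramp force range; bound clipped",
            stacklevel=2,
        )
    lo = float(np.clip(lo, 0.0, max_force))
    hi = float(np.clip(hi, 0.0, max_force))
    lo = min(lo, estimate.cf)
    hi = max(hi, estimate.cf)
    return replace(estimate, cf_lo=lo, cf_hi=hi)
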