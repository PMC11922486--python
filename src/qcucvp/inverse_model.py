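"""Reduced-order collapsible-vessel model and the per-frame inverse solve
that reconstructs a venous pressure waveform from segmented-area series.

Forward problem
---------------
The internal jugular vein (IJV) is modeled as a collapsible tube whose lumen
area is a monotone function of transmural pressure ``p_tm = p_internal -
p_external`` (mmHg):

* collapse branch (``p_tm <= 0``):   ``A = a_ref * exp(n_neg * p_tm / k)``
* distension branch (``p_tm > 0``):
  ``A = a_ref * (1 + (1/n_pos) * (1 - exp(-n_pos * n_neg * p_tm / k)))``

The two branches join with continuous slope at ``p_tm = 0`` where
``A = a_ref``.  Area vanishes smoothly as ``p_tm -> -inf`` (the 0.5 mm²
occlusion threshold is reached near -11 mmHg transmural for the default
vein-like stiffness ``k``) and saturates at ``a_ref * (1 + 1/n_pos)`` under distension,
mimicking a vein reaching its unfolded perimeter.  A power-law tube law with
the classic -3/2 collapse exponent was rejected here: driving a ~100 mm²
lumen below the 0.5 mm² occlusion threshold under such a law requires
hundreds of mmHg of negative transmural pressure, which is not what a
hand-held probe does to a neck vein.

External pressure on the IJV combines the probe's surface pressure and the
pulsating carotid artery lying against it:

``p_ext = transmission * force / contact_area  +  kappa * (p_carotid - carotid_ref_pressure)``

with the force term converted from N/cm² to mmHg.  The carotid itself is
stiff at venous pressure scales and is given a linear compliance about its
reference area.

Inverse problem
---------------
Given a measured IJV area, the known probe force and carotid pressure, the
internal (venous) pressure is the unique root of the monotone forward model;
``invert_frame`` brackets it with Brent's method.  ``estimate_cvp_waveform``
runs the inversion per frame over a constant-force hold and first calibrates
the tube stiffness ``k`` so the reconstructed waveform's time-mean equals
the collapse-force-based mean CVP estimate used as the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .signal_processing import TimeSeries

__all__ = [
    "VesselParams",
    "ForwardInputs",
    "InverseResult",
    "N_PER_CM2_TO_MMHG",
    "tube_law_area",
    "tube_law_pressure",
    "probe_pressure_mmhg",
    "forward_areas",
    "invert_frame",
    "estimate_cvp_waveform",
]

#: 1 N/cm² = 10 kPa = 75.006 mmHg.
N_PER_CM2_TO_MMHG = 1e4 / 133.322


@dataclass(frozen=True)
class VesselParams:
    """Geometry, tube-law and coupling parameters of the IJV/carotid pair.

    Defaults describe a vein-like IJV of ~1 cm² relaxed lumen under a
    large-footprint probe; they are plausible round numbers, not fitted
    patient values.
    """

    a_ref: float = 100.0          # unstressed IJV lumen area, mm²
    k_stiff: float = 2.0          # tube-law stiffness scale, mmHg
    n_pos: float = 2.0            # distension saturation exponent
    n_neg: float = 1.0            # collapse steepness exponent
    contact_area: float = 15.0    # probe footprint, cm²
    transmission: float = 0.4     # fraction of surface pressure reaching the vessel
    kappa: float = 0.02           # carotid-to-IJV pressure coupling fraction
    carotid_a_ref: float = 50.0   # carotid lumen area at reference pressure, mm²
    carotid_compliance: float = 0.25   # mm² per mmHg about the reference
    carotid_ref_pressure: float = 70.0  # carotid end-diastolic reference, mmHg

    def __post_init__(self) -> None:
        if self.a_ref <= 0 or self.k_stiff <= 0 or self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("a_ref, k_stiff, n_pos, n_neg must be positive")
        if not (0 < self.transmission <= 1):
            raise ValueError("transmission must be in (0, 1]")
        if self.contact_area <= 0:
            raise ValueError("contact_area must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def max_area(self) -> float:
        """Supremum of attainable IJV area (distension saturation), mm²."""
        return self.a_ref * (1.0 + 1.0 / self.n_pos)

    @property
    def mmhg_per_newton(self) -> float:
        return self.transmission / self.contact_area * N_PER_CM2_TO_MMHG


@dataclass(frozen=True)
class ForwardInputs:
    p_ijv: float       # venous internal pressure, mmHg
    p_carotid: float   # carotid internal pressure, mmHg
    probe_force: float  # N, >= 0
    vessel: VesselParams

    def __post_init__(self) -> None:
        if self.probe_force < 0:
            raise ValueError("probe_force must be >= 0")


@dataclass(frozen=True)
class InverseResult:
    cvp_waveform: TimeSeries
    per_frame_area_residual: np.ndarray  # mm², NaN on unconverged frames
    anchor_mean: float
    converged_frames: int
    k_stiff_calibrated: float
    unconverged_mask: np.ndarray


def tube_law_area(p_tm, vessel: VesselParams):
    """Lumen area (mm²) at transmural pressure ``p_tm`` (mmHg). Vectorized."""
    p = np.asarray(p_tm, dtype=float)
    s = vessel.n_neg / vessel.k_stiff
    neg = vessel.a_ref * np.exp(s * np.minimum(p, 0.0))
    pos = vessel.a_ref * (
        1.0 + (1.0 - np.exp(-vessel.n_pos * s * np.maximum(p, 0.0))) / vessel.n_pos
    )
    out = np.where(p <= 0.0, neg, pos)
    return out if out.ndim else float(out)

def tube_law_pressure(area, vessel: VesselParams):
    """Transmural pressure (mmHg) at lumen area ``area`` (mm²); inverse of
    :func:`tube_law_area`.  NaN outside the attainable range (0, max_area)."""
    a = np.asarray(area, dtype=float)
    r = a / vessel.a_ref
    k = vessel.k_stiff / vessel.n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        neg = k * np.log(r)
        arg = 1.0 - vessel.n_pos * (r - 1.0)
        pos = -k / vessel.n_pos * np.log(arg)
        out = np.where(r <= 1.0, neg, pos)
        out = np.where((a <= 0) | (arg <= 0), np.nan, out)
    return out if out.ndim else float(out)


def probe_pressure_mmhg(force_n, vessel: VesselParams):
    """Surface pressure reaching the vessel for a given probe force (N)."""
    return np.asarray(force_n, dtype=float) * vessel.mmhg_per_newton


def external_pressure(force_n, p_carotid, vessel: VesselParams):
    """Total external pressure on the IJV: probe plus carotid coupling."""
    p_car = np.asarray(p_carotid, dtype=float)
    return probe_pressure_mmhg(force_n, vessel) + vessel.kappa * (
        p_car - vessel.carotid_ref_pressure
    )


def forward_areas(inputs: ForwardInputs) -> Mapping[str, float]:
    """IJV and carotid cross-sectional areas (mm²) for the given pressures
    and probe force."""
    v = inputs.vessel
    p_ext = external_pressure(inputs.probe_force, inputs.p_carotid, v)
    ijv = tube_law_area(inputs.p_ijv - p_ext, v)
    carotid = max(
        v.carotid_a_ref + v.carotid_compliance * (inputs.p_carotid - v.carotid_ref_pressure),
        0.0,
    )
    return {"ijv_area": float(ijv), "carotid_area": float(carotid)}


def invert_frame(
    measured_area: float,
    p_carotid: float,
    probe_force: float,
    vessel: VesselParams,
    bracket: tuple[float, float] = (-5.0, 40.0),
    tol_mm2: float | None = None,
) -> float:
    """Venous pressure (mmHg) whose forward IJV area matches ``measured_area``.

    The forward model is strictly increasing in venous pressure, so the root
    is bracketed and found with Brent's method; convergence is declared when
    the forward area is within ``tol_mm2`` (default ``1e-3 * a_ref``) of the
    measurement.

    Raises ValueError("unconverged frame ...") when the measured area is not
    attainable for any venous pressure within the bracket.
    """
    if tol_mm2 is None:
        tol_mm2 = 1e-3 * vessel.a_ref

    def resid(p_ijv: float) -> float:
        return (
            forward_areas(ForwardInputs(p_ijv, p_carotid, probe_force, vessel))["ijv_area"]
            - measured_area
        )

    lo, hi = bracket
    rlo, rhi = resid(lo), resid(hi)
    if abs(rlo) <= tol_mm2:
        return float(lo)
    if abs(rhi) <= tol_mm2:
        return float(hi)
    if rlo > 0 or rhi < 0:
        raise ValueError(
            f"unconverged frame: area {measured_area:.3f} mm² outside attainable "
            f"range for bracket {bracket}"
        )
    p = brentq(resid, lo, hi, xtol=1e-10)
    assert abs(resid(p)) <= tol_mm2, "monotone tube law must converge"
    return float(p)


def _pressure_slope_coeff(areas: np.ndarray, vessel: VesselParams) -> np.ndarray:
    """Per-frame coefficient c such that the inverted venous pressure is
    ``p_ext + k_stiff * c`` — linear in stiffness, which makes the mean
    anchoring a one-step solve.  NaN where the area is unattainable."""
    unit = replace(vessel, k_stiff=1.0)
    return tube_law_pressure(areas, unit)


def estimate_cvp_waveform(
    ijv_area: TimeSeries,
    force: TimeSeries,
    carotid_pressure: TimeSeries,
    anchor_cvp: float,
    vessel: VesselParams,
    bracket: tuple[float, float] = (-5.0, 40.0),
    tol_mm2: float | None = None,
    anchor_tol: float = 0.1,
    max_unconverged_frac: float = 0.2,
    smooth_s: float = 0.1,
) -> InverseResult:
    """Reconstruct the CVP waveform over a constant-force hold.

    Measured areas are first smoothed with a short moving average
    (``smooth_s`` seconds) to suppress frame-segmentation noise; this also
    slightly attenuates the sharpest cardiac components, so reconstructed
    waveforms are mildly dampened versions of the truth, with the fastest
    a/c morphology least distinct.  Per frame, venous pressure is the root
    of the forward model at the (smoothed) measured IJV area
    (:func:`invert_frame`).  Before the per-frame pass the
    tube stiffness ``k_stiff`` is calibrated (one-dimensional, exact for
    this law since the inverted pressure is affine in ``k_stiff``) so that
    the reconstruction's time-mean equals ``anchor_cvp`` within
    ``anchor_tol`` — the anchoring role the collapse-force-based mean CVP
    estimate plays as the inverse model's initial condition.

    Unattainable frames are flagged, linearly interpolated, and counted;
    more than ``max_unconverged_frac`` of them is a failure.
    """
    n = len(ijv_area)
    if len(force) != n or len(carotid_pressure) != n:
        raise ValueError("ijv_area, force and carotid_pressure must be frame-aligned")

    areas = ijv_area.values
    w = max(int(round(smooth_s / ijv_area.dt)), 1)
    if w > 1:
        kernel = np.ones(w) / w
        pad = np.concatenate([np.full(w, areas[0]), areas, np.full(w, areas[-1])])
        areas = np.convolve(pad, kernel, mode="same")[w:-w]
    coeff = _pressure_slope_coeff(areas, vessel)
    bad = ~np.isfinite(coeff)
    n_bad = int(bad.sum())
    if n_bad > max_unconverged_frac * n:
        raise ValueError(
            f"inverse solve failed: {n_bad}/{n} frames outside the attainable "
            f"area range (0, {vessel.max_area:.1f} mm²)"
        )
    ok = ~bad
    p_ext = external_pressure(force.values, carotid_pressure.values, vessel)

    mean_coeff = float(np.mean(coeff[ok]))
    if abs(mean_coeff) < 1e-12:
        raise ValueError("cannot anchor: areas sit exactly at the reference area on average")
    k_star = (anchor_cvp - float(np.mean(p_ext[ok]))) / mean_coeff
    if k_star <= 0:
        raise ValueError(
            "cannot anchor: requested mean CVP is on the wrong side of the "
            "external pressure for this capture"
        )
    calibrated = replace(vessel, k_stiff=k_star)

    pressures = np.full(n, np.nan)
    residuals = np.full(n, np.nan)
    for i in np.flatnonzero(ok):
        try:
            p = invert_frame(
                float(areas[i]), float(carotid_pressure.values[i]),
                float(force.values[i]), calibrated, bracket=bracket, tol_mm2=tol_mm2,
            )
        except ValueError:
            ok[i] = False
            continue
        pressures[i] = p
        residuals[i] = (
            forward_areas(
                ForwardInputs(p, float(carotid_pressure.values[i]),
                              float(force.values[i]), calibrated)
            )["ijv_area"]
            - areas[i]
        )
    unconverged = ~ok
    n_bad = int(unconverged.sum())
    if n_bad > max_unconverged_frac * n:
        raise ValueError(f"inverse solve failed: {n_bad}/{n} unconverged frames")
    if n_bad:
        t = ijv_area.t
        pressures[unconverged] = np.interp(t[unconverged], t[ok], pressures[ok])

    waveform = TimeSeries(ijv_area.t0, ijv_area.dt, pressures, units="mmHg")
    mean = waveform.mean()
    if abs(mean - anchor_cvp) > anchor_tol:
        raise ValueError(
            f"anchoring failed: reconstructed mean {mean:.3f} mmHg vs anchor "
            f"{anchor_cvp:.3f} mmHg (unconverged frames may bias the mean)"
        )
    return InverseResult(
        cvp_waveform=waveform,
        per_frame_area_residual=residuals,
        anchor_mean=mean,
        converged_frames=n - n_bad,
        k_stiff_calibrated=k_star,
        unconverged_mask=unconverged,
    )
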