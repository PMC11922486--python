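"""Synthetic physiological waveforms and compression-ultrasound captures.

These generators stand in for bedside data: central venous pressure (CVP)
waveforms with the canonical a/c/x/v/y morphology plus sinusoidal
respiratory modulation, simplified two-level carotid pressure pulses, and
full quantitative-compression-ultrasound (QCU) captures — a probe-force
protocol (pre-contact, sync spikes, ramp to occlusion, constant-force hold)
with frame-synchronous IJV and carotid areas produced by the forward
collapsible-tube model.  Ground truth (true CVP waveform, true collapse
force, inserted force/frame lag) is carried on the capture so downstream
estimators can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .inverse_model import (
    VesselParams,
    external_pressure,
    tube_law_area,
    tube_law_pressure,
)
from .signal_processing import TimeSeries

__all__ = [
    "CVPWaveformSpec",
    "CaptureProtocol",
    "QCUCapture",
    "CohortPopulation",
    "VesselParams",
    "COMPONENT_PHASE",
    "COMPONENT_WIDTH_FRAC",
    "synth_cvp_waveform",
    "synth_carotid_pressure",
    "synth_capture",
    "synth_cohort",
    "OCCLUSION_THRESHOLD_MM2",
]

OCCLUSION_THRESHOLD_MM2 = 0.5

#: Intra-beat phase (fraction of the RR interval) of each right-atrial
#: waveform component: a (atrial contraction), c (tricuspid closure),
#: x (atrial relaxation descent), v (atrial filling), y (passive emptying
#: descent).  a and c sit in ventricular diastole, v in systole.
COMPONENT_PHASE: Mapping[str, float] = {"a": 0.10, "c": 0.25, "x": 0.40, "v": 0.65, "y": 0.85}

#: Gaussian bump width as a fraction of the RR interval.
COMPONENT_WIDTH_FRAC = 0.05

_DEFAULT_AMPLITUDES: Mapping[str, float] = {"a": 1.5, "c": 0.8, "x": 1.0, "v": 1.2, "y": 0.8}


@dataclass(frozen=True)
class CVPWaveformSpec:
    """Parameters of a synthetic CVP waveform.

    ``component_amplitudes`` holds non-negative magnitudes for the a/c/v
    peaks and the x/y descents (descents are applied with negative sign).
    Respiratory modulation is an additive sinusoid of ``resp_amplitude``
    (peak, mmHg); its period ``60/resp_rate`` must exceed 1 s so cardiac and
    respiratory content stay on opposite sides of the 1 Hz band boundary.
    """

    mean_cvp: float = 5.0           # mmHg
    heart_rate: float = 75.0        # beats/min
    resp_rate: float = 12.0         # breaths/min
    resp_amplitude: float = 1.0     # mmHg
    component_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES)
    )
    noise_sd: float = 0.1           # mmHg
    duration: float = 30.0          # s
    sample_rate: float = 100.0      # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0 or self.resp_rate <= 0:
            raise ValueError("heart_rate and resp_rate must be positive")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if 60.0 / self.resp_rate <= 1.0:
            raise ValueError("respiratory period must exceed 1 s")
        if self.duration * self.heart_rate / 60.0 < 2:
            raise ValueError("duration must cover at least 2 cardiac cycles")
        if self.noise_sd < 0 or self.resp_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


def _cardiac_component(t: np.ndarray, heart_rate: float,
                       amplitudes: Mapping[str, float]) -> np.ndarray:
    """Zero-mean per-beat a/c/x/v/y morphology (sum of signed Gaussian bumps)."""
    period = 60.0 / heart_rate
    phase = (t / period) % 1.0
    width = COMPONENT_WIDTH_FRAC
    y = np.zeros_like(t)
    for name, center in COMPONENT_PHASE.items():
        amp = float(amplitudes.get(name, 0.0))
        if amp == 0.0:
            continue
        sign = -1.0 if name in ("x", "y") else 1.0
        # wrap the bump across beat boundaries
        d = phase - center
        d = np.minimum(np.abs(d), 1.0 - np.abs(d))
        y += sign * amp * np.exp(-0.5 * (d / width) ** 2)
    if y.any():
        y -= y.mean()
    return y


def synth_cvp_waveform(spec: CVPWaveformSpec) -> TimeSeries:
    """Synthesize a CVP waveform: mean + cardiac morphology + respiratory
    sinusoid + white Gaussian noise.  Deterministic for a given seed."""
    n = int(round(spec.duration * spec.sample_rate))
    dt = 1.0 / spec.sample_rate
    t = dt * np.arange(n)
    cardiac = _cardiac_component(t, spec.heart_rate, spec.component_amplitudes)
    resp = spec.resp_amplitude * np.sin(2.0 * np.pi * t * spec.resp_rate / 60.0)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
    return TimeSeries(0.0, dt, spec.mean_cvp + cardiac + resp + noise, units="mmHg")


def synth_carotid_pressure(
    duration: float,
    sample_rate: float,
    heart_rate: float = 75.0,
    p_dia: float = 70.0,
    p_sys: float = 110.0,
    systole: tuple[float, float] = (0.35, 0.75),
    smooth_frac: float = 0.04,
) -> TimeSeries:
    """Simplified carotid pressure: a two-level per-beat pulse highlighting
    end-diastole and peak-systole, with smoothed transitions.

    ``systole`` gives the systolic window as fractions of the RR interval;
    the default places carotid systole over the venous v wave and leaves the
    a/c complex in diastole.
    """
    n = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    t = dt * np.arange(n)
    period = 60.0 / heart_rate
    phase = (t / period) % 1.0
    s0, s1 = systole
    w = smooth_frac
    # smooth rectangular pulse via two logistic edges
    pulse = 1.0 / (1.0 + np.exp(-(phase - s0) / w)) - 1.0 / (1.0 + np.exp(-(phase - s1) / w))
    return TimeSeries(0.0, dt, p_dia + (p_sys - p_dia) * pulse, units="mmHg")


@dataclass(frozen=True)
class CaptureProtocol:
    """Force protocol of one QCU acquisition.

    Phases: light pre-contact, a quick sync compression, a slow linear ramp
    until well past occlusion, release, a constant-force hold with the vein
    lightly compressed, a closing sync compression, and release.  The study
    protocol names the maneuvers; the numbers here (ramp rate, durations,
    spike shape) are the generator's own defaults, documented as such.
    """

    ramp_rate: float = 1.5        # N/s
    max_ramp_force: float = 20.0  # N, error if occlusion not reached below this
    hold_force: float = 3.5       # N
    pre_s: float = 2.0
    hold_s: float = 15.0
    post_s: float = 1.5
    spike_force: float = 6.0      # N, quick-compression sync transient
    spike_s: float = 0.4
    contact_force: float = 0.3    # N, light pre/post contact
    force_noise_sd: float = 0.02  # N
    area_noise_sd: float = 0.0    # mm², frame segmentation noise
    sync_lag_s: float = 0.0       # inserted force-vs-frames clock offset


@dataclass(frozen=True)
class QCUCapture:
    """Synchronized (up to ``protocol.sync_lag_s``) force and area channels
    of one acquisition, with per-sample phase labels and synthetic truth."""

    force: TimeSeries              # N
    ijv_area: TimeSeries           # mm²
    carotid_area: TimeSeries       # mm²
    phase_labels: np.ndarray       # str per sample: pre/sync_spike/ramp/hold/post
    sample_rate: float
    true_cvp: TimeSeries | None = None
    true_cf: float | None = None          # N, first ramp force with area < threshold
    true_collapse_time: float | None = None
    carotid_pressure: TimeSeries | None = None
    vessel: VesselParams | None = None
    protocol: CaptureProtocol | None = None

    def phase_slice(self, phase: str) -> slice:
        idx = np.flatnonzero(self.phase_labels == phase)
        if idx.size == 0:
            raise ValueError(f"capture has no '{phase}' phase")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def save(self, directory: str | Path) -> None:
        """Serialize as a directory of CSV channels plus a JSON sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.force.to_csv(d / "force.csv")
        self.ijv_area.to_csv(d / "ijv_area.csv")
        self.carotid_area.to_csv(d / "carotid_area.csv")
        if self.true_cvp is not None:
            self.true_cvp.to_csv(d / "true_cvp.csv")
        if self.carotid_pressure is not None:
            self.carotid_pressure.to_csv(d / "carotid_pressure.csv")
        meta = {
            "sample_rate": self.sample_rate,
            "phase_labels": self.phase_labels.tolist(),
            "true_cf": self.true_cf,
            "true_collapse_time": self.true_collapse_time,
            "vessel": asdict(self.vessel) if self.vessel else None,
            "protocol": asdict(self.protocol) if self.protocol else None,
        }
        (d / "capture.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "QCUCapture":
        d = Path(directory)
        meta = json.loads((d / "capture.json").read_text())
        def _opt(name: str, units: str) -> TimeSeries | None:
            p = d / name
            return TimeSeries.from_csv(p, units) if p.exists() else None
        return cls(
            force=TimeSeries.from_csv(d / "force.csv", "N"),
            ijv_area=TimeSeries.from_csv(d / "ijv_area.csv", "mm2"),
            carotid_area=TimeSeries.from_csv(d / "carotid_area.csv", "mm2"),
            phase_labels=np.array(meta["phase_labels"]),
            sample_rate=float(meta["sample_rate"]),
            true_cvp=_opt("true_cvp.csv", "mmHg"),
            true_cf=meta.get("true_cf"),
            true_collapse_time=meta.get("true_collapse_time"),
            carotid_pressure=_opt("carotid_pressure.csv", "mmHg"),
            vessel=VesselParams(**meta["vessel"]) if meta.get("vessel") else None,
            protocol=CaptureProtocol(**meta["protocol"]) if meta.get("protocol") else None,
        )


def _force_profile(protocol: CaptureProtocol, ramp_s: float, sample_rate: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise force time series and per-sample phase labels."""
    dt = 1.0 / sample_rate
    segments: list[tuple[str, np.ndarray]] = []
    p = protocol

    def flat(label: str, value: float, dur: float) -> None:
        segments.append((label, np.full(int(round(dur / dt)), value)))

    def spike() -> None:
        n = int(round(p.spike_s / dt))
        shape = np.sin(np.linspace(0.0, np.pi, n)) ** 2
        segments.append(("sync_spike", p.contact_force + (p.spike_force - p.contact_force) * shape))

    flat("pre", p.contact_force, p.pre_s)
    spike()
    flat("pre", p.contact_force, 0.6)
    n_ramp = int(round(ramp_s / dt))
    segments.append(("ramp", p.contact_force + p.ramp_rate * dt * np.arange(n_ramp)))
    flat("hold", p.hold_force, p.hold_s)
    spike()
    flat("post", p.contact_force, p.post_s)

    labels = np.concatenate([np.full(len(v), lab) for lab, v in segments])
    force = np.concatenate([v for _, v in segments])
    if p.force_noise_sd > 0:
        force = force + rng.normal(0.0, p.force_noise_sd, len(force))
    return np.maximum(force, 0.0), labels


def synth_capture(
    mean_cvp: float,
    vessel: VesselParams,
    protocol: CaptureProtocol | None = None,
    cvp_spec: CVPWaveformSpec | None = None,
    seed: int = 0,
    carotid: TimeSeries | None = None,
) -> QCUCapture:
    """Generate one QCU capture for a subject with the given true mean CVP.

    The true CVP waveform drives the forward collapsible-tube model sample
    by sample under the protocol's force profile and the carotid coupling;
    the recorded ground-truth collapse force is the force at the first ramp
    sample whose modeled area drops below the 0.5 mm² occlusion threshold.
    ``protocol.sync_lag_s`` shifts the area channels' clock relative to the
    force channel to emulate unsynchronized acquisition hardware.
    """
    protocol = protocol or CaptureProtocol()
    rng = np.random.default_rng(seed)

    # hold must leave the vein lightly compressed, not occluded, at mean CVP
    hold_area = tube_law_area(
        mean_cvp - protocol.hold_force * vessel.mmhg_per_newton, vessel
    )
    if hold_area < OCCLUSION_THRESHOLD_MM2:
        raise ValueError(
            f"hold_force {protocol.hold_force} N fully occludes at mean CVP {mean_cvp} mmHg"
        )

    # ramp well past nominal occlusion so the upper area envelope also
    # reaches the threshold within the recorded ramp
    occl_tm = tube_law_pressure(OCCLUSION_THRESHOLD_MM2, vessel)
    f_occl = (mean_cvp - occl_tm + vessel.kappa * 45.0) / vessel.mmhg_per_newton
    if f_occl > protocol.max_ramp_force:
        raise ValueError(
            f"protocol never reaches occlusion during ramp: needs ~{f_occl:.1f} N "
            f"> max_ramp_force {protocol.max_ramp_force} N"
        )
    ramp_s = min(
        (f_occl + 4.0 - protocol.contact_force) / protocol.ramp_rate,
        (protocol.max_ramp_force - protocol.contact_force) / protocol.ramp_rate,
    )

    if cvp_spec is None:
        cvp_spec = CVPWaveformSpec(mean_cvp=mean_cvp, seed=seed)
    else:
        cvp_spec = CVPWaveformSpec(**{**asdict(cvp_spec), "mean_cvp": mean_cvp, "seed": seed})

    force_vals, labels = _force_profile(protocol, ramp_s, cvp_spec.sample_rate, rng)
    n = len(force_vals)
    dt = 1.0 / cvp_spec.sample_rate
    duration = n * dt

    full_spec = CVPWaveformSpec(**{**asdict(cvp_spec), "duration": duration})
    cvp = synth_cvp_waveform(full_spec)
    if carotid is None:
        carotid = synth_carotid_pressure(duration, cvp_spec.sample_rate,
                                         heart_rate=cvp_spec.heart_rate)
    p_ext = external_pressure(force_vals, carotid.values[:n], vessel)
    ijv = tube_law_area(cvp.values[:n] - p_ext, vessel)
    carotid_area = np.maximum(
        vessel.carotid_a_ref
        + vessel.carotid_compliance * (carotid.values[:n] - vessel.carotid_ref_pressure),
        0.0,
    )
    if protocol.area_noise_sd > 0:
        ijv = np.maximum(ijv + rng.normal(0.0, protocol.area_noise_sd, n), 0.0)
        carotid_area = np.maximum(
            carotid_area + rng.normal(0.0, protocol.area_noise_sd, n), 0.0
        )

    ramp = labels == "ramp"
    below = ramp & (ijv < OCCLUSION_THRESHOLD_MM2)
    if not below.any():
        raise ValueError("protocol never reaches occlusion during ramp")
    i0 = int(np.flatnonzero(below)[0])
    true_cf = float(force_vals[i0])
    true_collapse_time = float(i0 * dt)

    # a positive sync lag delays the frame channel: frame i shows the state
    # from lag seconds earlier, emulating unsynchronized acquisition clocks
    n_lag = int(round(protocol.sync_lag_s * cvp_spec.sample_rate))
    if n_lag:
        ijv = np.concatenate([np.full(n_lag, ijv[0]), ijv[:-n_lag]]) if n_lag > 0 else \
            np.concatenate([ijv[-n_lag:], np.full(-n_lag, ijv[-1])])
        carotid_area = np.concatenate([np.full(n_lag, carotid_area[0]), carotid_area[:-n_lag]]) \
            if n_lag > 0 else np.concatenate([carotid_area[-n_lag:], np.full(-n_lag, carotid_area[-1])])
    return QCUCapture(
        force=TimeSeries(0.0, dt, force_vals, "N"),
        ijv_area=TimeSeries(0.0, dt, ijv, "mm2"),
        carotid_area=TimeSeries(0.0, dt, carotid_area, "mm2"),
        phase_labels=labels,
        sample_rate=cvp_spec.sample_rate,
        true_cvp=cvp.with_values(cvp.values[:n]),
        true_cf=true_cf,
        true_collapse_time=true_collapse_time,
        carotid_pressure=carotid.with_values(carotid.values[:n]),
        vessel=vessel,
        protocol=protocol,
    )


@dataclass(frozen=True)
class CohortPopulation:
    """Population distributions for a synthetic cohort.

    Mean CVPs are evenly spread over ``cvp_range`` (the study cohort spans
    0.5 to 10.5 mmHg) with seeded jitter; inclination angles are uniform
    over ``theta_range_deg`` (semi-supine postures).
    """

    cvp_range: tuple[float, float] = (0.5, 10.5)
    cvp_jitter: float = 0.0
    theta_range_deg: tuple[float, float] = (10.0, 40.0)
    vessel: VesselParams = field(default_factory=VesselParams)
    a_ref_jitter_frac: float = 0.0
    resp_amplitude: float = 1.0
    noise_sd: float = 0.1
    jvp_height_rounding_cm: float = 1.0  # bedside heights read to the nearest cm


def synth_cohort(
    n_subjects: int,
    population: CohortPopulation | None = None,
    seed: int = 0,
) -> tuple["StudyTable", list[QCUCapture]]:
    """Generate an n-subject cohort: per-subject capture plus a study table
    of measured quantities (average invasive CVP, HO from the inclination
    angle, JVP where the pulsation head height is visible).

    The JVP entry applies the bedside geometry: the vertical height at which
    the venous column's pressure crosses zero is read along the neck at the
    subject's inclination, rounded to the population's height precision, and
    converted back to mmHg as height*sin(theta)*C.
    """
    from .calibration import CMH2O_TO_MMHG as _C, hydrostatic_offset
    from .study_data import JvpStatus, StudyTable, SubjectRecord, Vein

    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    population = population or CohortPopulation()
    rng = np.random.default_rng(seed)

    lo, hi = population.cvp_range
    cvps = np.linspace(lo, hi, n_subjects)
    if population.cvp_jitter > 0:
        cvps = cvps + rng.normal(0.0, population.cvp_jitter, n_subjects)
    elif n_subjects > 2 and hi == lo:
        import warnings

        warnings.warn("degenerate CVP distribution: regression design is singular")
    thetas = rng.uniform(*population.theta_range_deg, n_subjects)

    records, captures = [], []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        vessel = population.vessel
        if population.a_ref_jitter_frac > 0:
            from dataclasses import replace

            vessel = replace(
                vessel,
                a_ref=vessel.a_ref * (1 + rng.normal(0, population.a_ref_jitter_frac)),
            )
        spec = CVPWaveformSpec(
            mean_cvp=float(cvps[i]),
            resp_amplitude=population.resp_amplitude,
            noise_sd=population.noise_sd,
        )
        # per-subject hold force targeting a lightly compressed vein
        # (half the relaxed area) at that subject's mean CVP
        tm_target = tube_law_pressure(0.5 * vessel.a_ref, vessel)
        hold_force = (float(cvps[i]) - tm_target) / vessel.mmhg_per_newton
        protocol = CaptureProtocol(hold_force=max(hold_force, 0.5))
        cap = synth_capture(
            float(cvps[i]), vessel, protocol=protocol, cvp_spec=spec, seed=sub_seed
        )
        captures.append(cap)

        measured_cvp = float(np.mean(cap.true_cvp.values))
        theta = float(thetas[i])
        ho = hydrostatic_offset(theta)
        # bedside JVP: zero-pressure height (cmH2O column) read along the neck
        h_vertical_cm = max(measured_cvp, 0.0) / _C
        h_along = h_vertical_cm / np.sin(np.radians(theta))
        q = population.jvp_height_rounding_cm
        h_along = q * round(h_along / q) if q > 0 else h_along
        jvp = float(h_along * np.sin(np.radians(theta)) * _C)
        records.append(
            SubjectRecord(
                subject_id=i + 1,
                avg_invasive_cvp=round(measured_cvp, 2),
                vein=Vein.LIJ,
                collapse_force=round(cap.true_cf, 3),
                ho_cmh2o=round(ho, 2),
                jvp_status=JvpStatus.MEASURED,
                jvp_mmhg=round(jvp, 2),
            )
        )
    return StudyTable(records), captures
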