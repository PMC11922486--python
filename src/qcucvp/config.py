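"""Pipeline configuration: one YAML file with every constant the pipeline
uses, committed with defaults matching the study's stated values (0.5 mm²
occlusion threshold, 1 Hz cardiac/respiratory boundary, ±0.5 mmHg
hydrostatic and JVP uncertainties, 10-cm hydrostatic column, C = 0.7356)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CMH2O_TO_MMHG, HO_DISTANCE_CM
from .evaluation import HYDROSTATIC_UNCERT_MMHG, JVP_UNCERT_MMHG
from .inverse_model import VesselParams
from .synthetic_data import OCCLUSION_THRESHOLD_MM2

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    filter_cutoff_hz: float = 1.0
    collapse_threshold_mm2: float = OCCLUSION_THRESHOLD_MM2
    near_collapse_window_s: float = 5.0
    hydrostatic_uncert_mmhg: float = HYDROSTATIC_UNCERT_MMHG
    jvp_uncert_mmhg: float = JVP_UNCERT_MMHG
    ho_distance_cm: float = HO_DISTANCE_CM
    cmh2o_to_mmhg: float = CMH2O_TO_MMHG
    vessel: VesselParams = field(default_factory=VesselParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "filter_cutoff_hz",
            "collapse_threshold_mm2",
            "near_collapse_window_s",
            "hydrostatic_uncert_mmhg",
            "jvp_uncert_mmhg",
            "ho_distance_cm",
            "cmh2o_to_mmhg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        vessel = VesselParams(**raw.pop("vessel", {}))
        return cls(vessel=vessel, **raw)

    def save(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def describe(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
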