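"""Study cohort table: typed records, validation, and CSV/JSON round-trip I/O.

The bundled 11-subject table pairs each subject's catheter-measured average
central venous pressure (CVP, mmHg) with the noninvasive quantities acquired
at the bedside: the collapse force CF (N) of the compressed jugular vein, the
hydrostatic offset HO (cmH2O) implied by the bed inclination, the visually
estimated jugular venous pulsation height JVP (already converted to mmHg),
and the CVP predicted by a previously trained linear model.

JVP carries a three-way status: a numeric value when measured, ``X`` when the
pulsation top was looked for but could not be seen at the patient's
inclination, and ``-`` when measurement was not attempted.  Both sentinel
strings survive a write/load round trip unchanged.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "Vein",
    "JvpStatus",
    "SubjectRecord",
    "StudyTable",
    "load_study_table",
    "write_study_table",
    "load_demographics",
]

#: Table column order used for CSV and JSON serialization.
COLUMNS = [
    "#",
    "Avg. invasive CVP (mmHg)",
    "Vein",
    "CF (N)",
    "HO (cmH2O)",
    "CF Pred. CVP (mmHg)",
    "Multi-feature Pred. CVP (mmHg)",
    "JVP (mmHg)",
    "Trained model CVP (mmHg)",
]

REQUIRED_COLUMNS = COLUMNS[:5]


class Vein(str, enum.Enum):
    """Vein compressed during the capture (left/right internal/external jugular)."""

    LIJ = "LIJ"
    RIJ = "RIJ"
    LEJ = "LEJ"
    REJ = "REJ"

    @property
    def is_external(self) -> bool:
        return self in (Vein.LEJ, Vein.REJ)


class JvpStatus(enum.Enum):
    MEASURED = "measured"
    ATTEMPTED_UNMEASURABLE = "attempted_unmeasurable"  # written as "X"
    NOT_ATTEMPTED = "not_attempted"  # written as "-"


@dataclass(frozen=True)
class SubjectRecord:
    """One study row.

    ``jvp_mmhg`` is a float only when ``jvp_status`` is MEASURED; otherwise
    it is None and the status distinguishes "attempted but unmeasurable"
    from "not attempted".
    """

    subject_id: int
    avg_invasive_cvp: float
    vein: Vein
    collapse_force: float | None = None
    ho_cmh2o: float | None = None
    jvp_status: JvpStatus = JvpStatus.NOT_ATTEMPTED
    jvp_mmhg: float | None = None
    cf_pred_cvp: float | None = None
    multi_pred_cvp: float | None = None
    trained_model_cvp: float | None = None
    age_years: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.avg_invasive_cvp):
            raise ValueError(f"subject {self.subject_id}: avg_invasive_cvp must be finite")
        if self.collapse_force is not None and not self.collapse_force > 0:
            raise ValueError(f"subject {self.subject_id}: collapse_force must be > 0")
        if self.ho_cmh2o is not None and self.ho_cmh2o < 0:
            raise ValueError(f"subject {self.subject_id}: ho_cmh2o must be >= 0")
        if (self.jvp_status is JvpStatus.MEASURED) != (self.jvp_mmhg is not None):
            raise ValueError(
                f"subject {self.subject_id}: jvp_mmhg must be present iff status is MEASURED"
            )

    @property
    def theta_deg(self) -> float | None:
        """Inclination angle back-derived from HO = 10*sin(theta).

        The study prints HO, not theta, so this is a reconstruction of the
        angle under the fixed 10-cm right-atrium-to-neck distance assumption,
        not a measurement.
        """
        if self.ho_cmh2o is None:
            return None
        return math.degrees(math.asin(min(self.ho_cmh2o / 10.0, 1.0)))


@dataclass
class StudyTable:
    """Ordered collection of SubjectRecord with unique subject ids."""

    records: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate subject_id in study table")

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyTable):
            return NotImplemented
        return self.records == other.records

    def subject(self, subject_id: int) -> SubjectRecord:
        for r in self.records:
            if r.subject_id == subject_id:
                return r
        raise KeyError(f"no subject {subject_id}")

    def with_demographics(self, demo: pd.DataFrame) -> "StudyTable":
        """Attach Table-1 style demographics (indexed by subject id)."""
        out = []
        for r in self.records:
            if r.subject_id in demo.index:
                row = demo.loc[r.subject_id]
                r = replace(
                    r,
                    age_years=float(row["Age (years)"]),
                    height_cm=float(row["Height (cm)"]),
                    weight_kg=float(row["Weight (kg)"]),
                    sex=str(row["Sex"]),
                )
            out.append(r)
        return StudyTable(out)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            if r.jvp_status is JvpStatus.MEASURED:
                jvp = f"{r.jvp_mmhg:.2f}"
            elif r.jvp_status is JvpStatus.ATTEMPTED_UNMEASURABLE:
                jvp = "X"
            else:
                jvp = "-"
            rows.append(
                {
                    "#": r.subject_id,
                    "Avg. invasive CVP (mmHg)": r.avg_invasive_cvp,
                    "Vein": r.vein.value,
                    "CF (N)": r.collapse_force,
                    "HO (cmH2O)": r.ho_cmh2o,
                    "CF Pred. CVP (mmHg)": r.cf_pred_cvp,
                    "Multi-feature Pred. CVP (mmHg)": r.multi_pred_cvp,
                    "JVP (mmHg)": jvp,
                    "Trained model CVP (mmHg)": r.trained_model_cvp,
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS)


def _parse_jvp(cell: object) -> tuple[JvpStatus, float | None]:
    s = str(cell).strip()
    if s == "-" or s.lower() in ("nan", "none", ""):
        return JvpStatus.NOT_ATTEMPTED, None
    if s.upper() == "X":
        return JvpStatus.ATTEMPTED_UNMEASURABLE, None
    return JvpStatus.MEASURED, float(s)


def _opt_float(cell: object) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return None
    return float(s)


def _table_from_frame(df: pd.DataFrame) -> StudyTable:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            sid = int(row["#"])
            cvp = float(row["Avg. invasive CVP (mmHg)"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in a numeric column: {exc}") from exc
        status, jvp = _parse_jvp(row.get("JVP (mmHg)", "-"))
        records.append(
            SubjectRecord(
                subject_id=sid,
                avg_invasive_cvp=cvp,
                vein=Vein(str(row["Vein"]).strip()),
                collapse_force=_opt_float(row.get("CF (N)")),
                ho_cmh2o=_opt_float(row.get("HO (cmH2O)")),
                jvp_status=status,
                jvp_mmhg=jvp,
                cf_pred_cvp=_opt_float(row.get("CF Pred. CVP (mmHg)")),
                multi_pred_cvp=_opt_float(row.get("Multi-feature Pred. CVP (mmHg)")),
                trained_model_cvp=_opt_float(row.get("Trained model CVP (mmHg)")),
            )
        )
    return StudyTable(records)


def load_study_table(source: str | Path = "builtin") -> StudyTable:
    """Load the study table from the built-in fixture or a CSV/JSON file.

    ``source="builtin"`` returns the bundled 11-subject table.  A file path is
    dispatched on suffix: ``.json`` reads an array-of-objects export, anything
    else is read as CSV with the canonical header.
    """
    if source == "builtin":
        ref = resources.files("qcucvp.data") / "study_table.csv"
        with resources.as_file(ref) as p:
            return _table_from_frame(pd.read_csv(p, dtype={"JVP (mmHg)": str}))
    path = Path(source)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        if path.stat().st_size == 0:
            raise ValueError(f"missing required column(s): {REQUIRED_COLUMNS} (empty file)")
        df = pd.read_csv(path, dtype={"JVP (mmHg)": str})
    return _table_from_frame(df)


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write a table as CSV (default) or JSON array-of-objects (``.json``).

    JVP sentinels ``-`` / ``X`` are preserved so load(write(t)) == t.
    """
    path = Path(path)
    df = table.to_dataframe()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False, float_format="%.2f")


def load_demographics() -> pd.DataFrame:
    """Bundled demographics table, indexed by subject id. Stored for
    completeness; no calibration computation uses it."""
    ref = resources.files("qcucvp.data") / "demographics.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, index_col="#")
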