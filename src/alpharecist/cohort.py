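"""Typed cohort data model and delimited-text I/O.

A cohort is stored as two UTF-8 CSV files sharing a stem:

``<stem>.csv`` (one row per patient)
    patient_id, new_lesions, nontarget_status, afp_bl, afp_fu,
    rfs_months, rfs_event, os_months, os_event, percent_viable,
    reader1_category, reader2_category

``<stem>_lesions.csv`` (one row per lesion-timepoint)
    patient_id, lesion_id, organ, timepoint, longest_diameter_mm,
    viable_diameter_mm, is_target

Units are fixed: diameters in millimetres, survival times in months,
AFP in ng/ml.  Missing values are empty cells, never sentinel numbers.
Booleans are written as 0/1.  Numeric fields round-trip at full
precision (shortest-repr float formatting).

Validation is *total*: :func:`validate_record` returns a list of
violation descriptions and never raises; :func:`load_cohort` rejects
exactly the records for which that list is non-empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "Timepoint",
    "NontargetStatus",
    "LesionMeasurement",
    "AFPPair",
    "SurvivalOutcome",
    "PathologyRecord",
    "PatientRecord",
    "Cohort",
    "CohortError",
    "SchemaError",
    "CohortValidationError",
    "validate_record",
    "load_cohort",
    "write_cohort",
    "lesions_path_for",
]

# Minimum baseline longest diameter (mm) for a measurable target lesion.
TARGET_MIN_DIAMETER_MM = 10.0
MAX_TARGETS_PER_ORGAN = 2
MAX_TARGETS_TOTAL = 5


class CohortError(Exception):
    """Base error for cohort I/O and validation."""


class SchemaError(CohortError):
    """A required column is missing or a cell cannot be parsed."""


class CohortValidationError(CohortError):
    """One or more records violate the data-model invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class Timepoint(str, Enum):
    BASELINE = "baseline"
    FOLLOWUP = "followup"


class NontargetStatus(str, Enum):
    """Non-target lesion assessment; ABSENT means no non-target disease."""

    CR = "CR"
    NON_CR_NON_PD = "non-CR/non-PD"
    PD = "PD"
    ABSENT = "absent"


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion's total and arterial-enhancing (viable) longest diameters."""

    lesion_id: str
    organ: str
    timepoint: Timepoint
    longest_diameter: float  # mm
    viable_diameter: float  # mm, enhancing portion
    is_target: bool


@dataclass(frozen=True)
class AFPPair:
    """Serum alpha-fetoprotein (ng/ml) immediately before and after treatment."""

    afp_bl: float
    afp_fu: float


@dataclass(frozen=True)
class SurvivalOutcome:
    """Recurrence-free and overall survival from resection, in months."""

    rfs_months: float
    rfs_event: bool
    os_months: float
    os_event: bool


@dataclass(frozen=True)
class PathologyRecord:
    """Fraction (0..1) of residual viable tumor in the resected specimen."""

    percent_viable: float


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    lesions: tuple[LesionMeasurement, ...]
    new_lesions: bool
    nontarget_status: NontargetStatus
    survival: SurvivalOutcome
    afp: Optional[AFPPair] = None
    pathology: Optional[PathologyRecord] = None
    reader_categories: Optional[dict[str, str]] = None

    def baseline_lesions(self) -> list[LesionMeasurement]:
        return [l for l in self.lesions if l.timepoint is Timepoint.BASELINE]

    def followup_lesions(self) -> list[LesionMeasurement]:
        return [l for l in self.lesions if l.timepoint is Timepoint.FOLLOWUP]

    def __eq__(self, other):  # dict field makes the default eq fine; keep it
        return (
            isinstance(other, PatientRecord)
            and self.patient_id == other.patient_id
            and self.lesions == other.lesions
            and self.new_lesions == other.new_lesions
            and self.nontarget_status == other.nontarget_status
            and self.survival == other.survival
            and self.afp == other.afp
            and self.pathology == other.pathology
            and (self.reader_categories or None) == (other.reader_categories or None)
        )


@dataclass
class Cohort:
    records: list[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def validate_record(record: PatientRecord) -> list[str]:
    """Return all invariant violations for one patient (empty list = valid).

    Never raises; each message names the offending field and the rule.
    """
    v: list[str] = []
    pid = record.patient_id

    for les in record.lesions:
        tag = f"patient {pid} lesion {les.lesion_id} ({les.timepoint.value})"
        if not _finite(les.longest_diameter) or les.longest_diameter < 0:
            v.append(f"{tag}: longest_diameter must be finite and >= 0 mm")
            continue
        if not _finite(les.viable_diameter) or les.viable_diameter < 0:
            v.append(f"{tag}: viable_diameter must be finite and >= 0 mm")
            continue
        if les.viable_diameter > les.longest_diameter:
            v.append(f"{tag}: viable_diameter exceeds longest_diameter")
        if (
            les.is_target
            and les.timepoint is Timepoint.BASELINE
            and les.longest_diameter < TARGET_MIN_DIAMETER_MM
        ):
            v.append(
                f"{tag}: baseline target lesion below the {TARGET_MIN_DIAMETER_MM:g} mm "
                "measurability limit"
            )

    # every baseline target lesion needs a matched follow-up measurement
    fu_ids = {l.lesion_id for l in record.followup_lesions()}
    for les in record.baseline_lesions():
        if les.is_target and les.lesion_id not in fu_ids:
            v.append(
                f"patient {pid}: baseline target lesion {les.lesion_id} "
                "has no follow-up measurement"
            )

    # target-lesion count limits: at most two per organ and five in total
    targets = [l for l in record.baseline_lesions() if l.is_target]
    if len(targets) > MAX_TARGETS_TOTAL:
        v.append(
            f"patient {pid}: {len(targets)} target lesions exceeds the limit of "
            f"five lesions in total"
        )
    per_organ: dict[str, int] = {}
    for les in targets:
        per_organ[les.organ] = per_organ.get(les.organ, 0) + 1
    for organ, cnt in per_organ.items():
        if cnt > MAX_TARGETS_PER_ORGAN:
            v.append(
                f"patient {pid}: {cnt} target lesions in organ '{organ}' exceeds "
                "the limit of two lesions per organ"
            )

    if record.afp is not None:
        if not _finite(record.afp.afp_bl) or record.afp.afp_bl <= 0:
            v.append(f"patient {pid}: afp_bl must be finite and > 0 ng/ml")
        if not _finite(record.afp.afp_fu) or record.afp.afp_fu < 0:
            v.append(f"patient {pid}: afp_fu must be finite and >= 0 ng/ml")

    s = record.survival
    if not _finite(s.rfs_months) or s.rfs_months < 0:
        v.append(f"patient {pid}: rfs_months must be finite and >= 0")
    if not _finite(s.os_months) or s.os_months < 0:
        v.append(f"patient {pid}: os_months must be finite and >= 0")
    if _finite(s.rfs_months) and _finite(s.os_months) and s.rfs_months > s.os_months:
        v.append(f"patient {pid}: rfs_months exceeds os_months")

    if record.pathology is not None:
        pv = record.pathology.percent_viable
        if not _finite(pv) or not (0.0 <= pv <= 1.0):
            v.append(f"patient {pid}: percent_viable must lie in [0, 1]")

    return v


# ---------------------------------------------------------------------------
# CSV I/O

PATIENT_COLUMNS = [
    "patient_id",
    "new_lesions",
    "nontarget_status",
    "afp_bl",
    "afp_fu",
    "rfs_months",
    "rfs_event",
    "os_months",
    "os_event",
    "percent_viable",
    "reader1_category",
    "reader2_category",
]

LESION_COLUMNS = [
    "patient_id",
    "lesion_id",
    "organ",
    "timepoint",
    "longest_diameter_mm",
    "viable_diameter_mm",
    "is_target",
]


def lesions_path_for(path: str | Path) -> Path:
    """Sibling lesion-table path for a patient-table path."""
    p = Path(path)
    return p.with_name(p.stem + "_lesions" + p.suffix)


def _parse_float(value, *, column: str, row: int, required: bool) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if required:
            raise SchemaError(f"row {row}: missing value in required column '{column}'")
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: non-numeric value {value!r} in column '{column}'")


def _parse_bool(value, *, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise SchemaError(f"row {row}: cannot parse boolean {value!r} in column '{column}'")


def load_cohort(path: str | Path, lesions_path: str | Path | None = None) -> Cohort:
    """Load and validate a cohort from its patient and lesion CSV files.

    Raises :class:`SchemaError` for structural problems (missing columns,
    unparseable cells) and :class:`CohortValidationError` when any record
    violates a data-model invariant (duplicated patient ids included).
    """
    path = Path(path)
    lesions_path = Path(lesions_path) if lesions_path else lesions_path_for(path)
    if not path.exists():
        raise CohortError(f"patient table not found: {path}")
    if not lesions_path.exists():
        raise CohortError(f"lesion table not found: {lesions_path}")

    patients = pd.read_csv(path, dtype=str, keep_default_na=False)
    lesions = pd.read_csv(lesions_path, dtype=str, keep_default_na=False)

    for col in PATIENT_COLUMNS:
        if col not in patients.columns:
            raise SchemaError(f"patient table is missing required column '{col}'")
    for col in LESION_COLUMNS:
        if col not in lesions.columns:
            raise SchemaError(f"lesion table is missing required column '{col}'")

    lesion_map: dict[str, list[LesionMeasurement]] = {}
    for i, row in lesions.iterrows():
        rownum = i + 2  # header is line 1
        tp = row["timepoint"].strip()
        try:
            timepoint = Timepoint(tp)
        except ValueError:
            raise SchemaError(
                f"row {rownum}: unknown timepoint {tp!r} (expected baseline/followup)"
            )
        les = LesionMeasurement(
            lesion_id=row["lesion_id"],
            organ=row["organ"],
            timepoint=timepoint,
            longest_diameter=_parse_float(
                row["longest_diameter_mm"], column="longest_diameter_mm",
                row=rownum, required=True),
            viable_diameter=_parse_float(
                row["viable_diameter_mm"], column="viable_diameter_mm",
                row=rownum, required=True),
            is_target=_parse_bool(row["is_target"], column="is_target", row=rownum),
        )
        lesion_map.setdefault(row["patient_id"], []).append(les)

    records: list[PatientRecord] = []
    seen: set[str] = set()
    violations: list[str] = []
    for i, row in patients.iterrows():
        rownum = i + 2
        pid = row["patient_id"]
        if pid in seen:
            violations.append(f"duplicate patient_id '{pid}' (row {rownum})")
            continue
        seen.add(pid)

        afp_bl = _parse_float(row["afp_bl"], column="afp_bl", row=rownum, required=False)
        afp_fu = _parse_float(row["afp_fu"], column="afp_fu", row=rownum, required=False)
        afp = AFPPair(afp_bl, afp_fu) if afp_bl is not None and afp_fu is not None else None

        pv = _parse_float(
            row["percent_viable"], column="percent_viable", row=rownum, required=False)
        pathology = PathologyRecord(pv) if pv is not None else None

        try:
            nts = NontargetStatus(row["nontarget_status"].strip())
        except ValueError:
            raise SchemaError(
                f"row {rownum}: unknown nontarget_status {row['nontarget_status']!r}")

        readers = {}
        for rk, col in (("reader1", "reader1_category"), ("reader2", "reader2_category")):
            if row[col].strip():
                readers[rk] = row[col].strip()

        record = PatientRecord(
            patient_id=pid,
            lesions=tuple(lesion_map.get(pid, [])),
            new_lesions=_parse_bool(row["new_lesions"], column="new_lesions", row=rownum),
            nontarget_status=nts,
            survival=SurvivalOutcome(
                rfs_months=_parse_float(
                    row["rfs_months"], column="rfs_months", row=rownum, required=True),
                rfs_event=_parse_bool(row["rfs_event"], column="rfs_event", row=rownum),
                os_months=_parse_float(
                    row["os_months"], column="os_months", row=rownum, required=True),
                os_event=_parse_bool(row["os_event"], column="os_event", row=rownum),
            ),
            afp=afp,
            pathology=pathology,
            reader_categories=readers or None,
        )
        violations.extend(validate_record(record))
        records.append(record)

    if violations:
        raise CohortValidationError(violations)
    return Cohort(records=records, provenance={"source": str(path)})


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to ``path`` (+ sibling lesion table); round-trips exactly.

    Missing AFP/pathology/reader values are written as empty cells.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    prow = []
    lrow = []
    for r in cohort.records:
        readers = r.reader_categories or {}
        prow.append({
            "patient_id": r.patient_id,
            "new_lesions": int(r.new_lesions),
            "nontarget_status": r.nontarget_status.value,
            "afp_bl": "" if r.afp is None else repr(float(r.afp.afp_bl)),
            "afp_fu": "" if r.afp is None else repr(float(r.afp.afp_fu)),
            "rfs_months": repr(float(r.survival.rfs_months)),
            "rfs_event": int(r.survival.rfs_event),
            "os_months": repr(float(r.survival.os_months)),
            "os_event": int(r.survival.os_event),
            "percent_viable": "" if r.pathology is None
            else repr(float(r.pathology.percent_viable)),
            "reader1_category": readers.get("reader1", ""),
            "reader2_category": readers.get("reader2", ""),
        })
        for les in r.lesions:
            lrow.append({
                "patient_id": r.patient_id,
                "lesion_id": les.lesion_id,
                "organ": les.organ,
                "timepoint": les.timepoint.value,
                "longest_diameter_mm": repr(float(les.longest_diameter)),
                "viable_diameter_mm": repr(float(les.viable_diameter)),
                "is_target": int(les.is_target),
            })

    pd.DataFrame(prow, columns=PATIENT_COLUMNS).to_csv(path, index=False)
    pd.DataFrame(lrow, columns=LESION_COLUMNS).to_csv(lesions_path_for(path), index=False)
    return path
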