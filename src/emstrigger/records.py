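"""Structured ambulance mission records and their CSV/JSON serialization.

One :class:`EMSRecord` describes a single ambulance mission: the dispatch
timeline, RETTS-A triage, the vital-sign panel, assessments and
interventions, drug administrations, the conveyance decision, environment
flags, and documentation-completeness flags used by the trigger rules.

Two on-disk formats are supported and round-trip losslessly:

* JSON — an array of nested record objects (the canonical form; a JSON
  Schema for it is available from :func:`record_json_schema`);
* CSV — UTF-8, comma-separated, ISO-8601 timestamps, one flattened row per
  record; list-valued fields (drugs, repeated vitals panels, the
  documentation map) are embedded as JSON strings in their cells.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .vocabulary import (
    ConveyanceMode,
    DefinitiveCareType,
    MissionType,
    Sex,
    SxabcdeStatus,
    SXABCDE_STEPS,
    TriageColour,
    Vocabulary,
)

logger = logging.getLogger(__name__)


class VitalObservation(BaseModel):
    """One set of vital-sign measurements; any value may be absent."""

    respiratory_rate: Optional[float] = None
    oxygen_saturation: Optional[float] = None
    systolic_bp: Optional[float] = None
    diastolic_bp: Optional[float] = None
    pulse: Optional[float] = None
    temperature: Optional[float] = None
    blood_glucose: Optional[float] = None


class TimedPanel(BaseModel):
    time: datetime
    values: VitalObservation


class VitalSignsPanel(VitalObservation):
    """Primary on-scene vitals plus any repeated panels during care."""

    repeated_panels: list[TimedPanel] = Field(default_factory=list)

    @field_validator("repeated_panels")
    @classmethod
    def _ordered(cls, v: list[TimedPanel]) -> list[TimedPanel]:
        times = [p.time for p in v]
        if times != sorted(times):
            raise ValueError("repeated_panels must be ordered by timestamp")
        return v


class DrugAdministration(BaseModel):
    drug_code: str
    dose: Optional[float] = None
    unit: Optional[str] = None
    route: Optional[str] = None
    indication: Optional[str] = None
    guideline_conform: Optional[bool] = None

    @field_validator("dose")
    @classmethod
    def _positive_dose(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("dose must be > 0 when present")
        return v


class CareDecision(BaseModel):
    conveyed: bool
    mode: ConveyanceMode = ConveyanceMode.none
    destination: Optional[str] = None
    destination_per_guideline: Optional[bool] = None

    @model_validator(mode="after")
    def _mode_consistent(self) -> "CareDecision":
        if not self.conveyed and self.mode is not ConveyanceMode.none:
            raise ValueError("non-conveyed record must have mode 'none'")
        if self.conveyed and self.mode is ConveyanceMode.none:
            raise ValueError("conveyed record must have a transport mode")
        return self


class EDHandover(BaseModel):
    physician_triage_colour: Optional[TriageColour] = None
    direct_to_definitive_care: bool = False
    definitive_care_type: DefinitiveCareType = DefinitiveCareType.none


class EnvironmentFlags(BaseModel):
    weather_affected_care: bool = False
    equipment_failure: bool = False
    resource_shortage: bool = False
    physical_harm_in_transport: bool = False
    drug_mixup: bool = False
    drug_shortage: bool = False
    language_barrier_present: bool = False
    interpreter_used: bool = False

    @model_validator(mode="after")
    def _interpreter_implies_barrier(self) -> "EnvironmentFlags":
        if self.interpreter_used and not self.language_barrier_present:
            raise ValueError(
                "interpreter_used requires language_barrier_present"
            )
        return self


class EMSRecord(BaseModel):
    """A single ambulance mission as documented in the journal system."""

    record_id: str
    patient_key: str = ""
    patient_age: int = Field(ge=0)
    patient_sex: Sex
    dispatch_priority: int = Field(ge=1, le=3)
    mission_start: datetime
    on_scene_arrival: Optional[datetime] = None
    scene_departure: Optional[datetime] = None
    triage_colour: TriageColour = TriageColour.missing
    chief_complaint: str = "other"
    vitals: VitalSignsPanel = Field(default_factory=VitalSignsPanel)
    examinations: set[str] = Field(default_factory=set)
    sxabcde_steps: dict[str, SxabcdeStatus] = Field(
        default_factory=lambda: {
            s: SxabcdeStatus.assessed_and_addressed for s in SXABCDE_STEPS
        }
    )
    drugs: list[DrugAdministration] = Field(default_factory=list)
    conveyance: CareDecision
    environment_flags: EnvironmentFlags = Field(default_factory=EnvironmentFlags)
    documentation: dict[str, bool] = Field(default_factory=dict)
    ed_handover: Optional[EDHandover] = None
    mission_type: MissionType = MissionType.primary_with_assessment
    deterioration_noted: bool = False
    manual_triggers: set[str] = Field(default_factory=set)

    @model_validator(mode="after")
    def _timeline_ordered(self) -> "EMSRecord":
        t0, t1, t2 = self.mission_start, self.on_scene_arrival, self.scene_departure
        if t1 is not None and t0 > t1:
            raise ValueError("mission_start must not be after on_scene_arrival")
        if t1 is not None and t2 is not None and t1 > t2:
            raise ValueError("on_scene_arrival must not be after scene_departure")
        return self

    @model_validator(mode="after")
    def _known_steps(self) -> "EMSRecord":
        unknown = set(self.sxabcde_steps) - set(SXABCDE_STEPS)
        if unknown:
            raise ValueError(f"unknown SX-ABCDE steps: {sorted(unknown)}")
        return self


def record_json_schema() -> dict[str, Any]:
    """JSON Schema for one record object (arrays of these form a file)."""
    return EMSRecord.model_json_schema()


# ---------------------------------------------------------------------------
# Parsing and writing


@dataclass(frozen=True)
class ParseIssue:
    """A validation problem located at a row (and field where known)."""

    row: int
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: {self.field}: {self.message}"


@dataclass
class ParseResult:
    records: list[EMSRecord] = field(default_factory=list)
    errors: list[ParseIssue] = field(default_factory=list)

    def raise_on_error(self) -> list[EMSRecord]:
        if self.errors:
            msgs = "; ".join(str(e) for e in self.errors[:10])
            raise ValueError(f"{len(self.errors)} parse error(s): {msgs}")
        return self.records


_JSON_CELL_FIELDS = ("drugs", "repeated_panels", "documentation")
_VITAL_FIELDS = (
    "respiratory_rate",
    "oxygen_saturation",
    "systolic_bp",
    "diastolic_bp",
    "pulse",
    "temperature",
    "blood_glucose",
)
_FLAG_FIELDS = tuple(EnvironmentFlags.model_fields)

CSV_COLUMNS: tuple[str, ...] = (
    "record_id",
    "patient_key",
    "patient_age",
    "patient_sex",
    "dispatch_priority",
    "mission_type",
    "mission_start",
    "on_scene_arrival",
    "scene_departure",
    "triage_colour",
    "chief_complaint",
    *(f"vital_{v}" for v in _VITAL_FIELDS),
    "repeated_panels",
    "examinations",
    *(f"sxabcde_{s}" for s in SXABCDE_STEPS),
    "drugs",
    "conveyed",
    "conveyance_mode",
    "destination",
    "destination_per_guideline",
    *(f"flag_{f}" for f in _FLAG_FIELDS),
    "documentation",
    "ed_physician_triage_colour",
    "ed_direct_to_definitive_care",
    "ed_definitive_care_type",
    "deterioration_noted",
    "manual_triggers",
)


def _fmt_opt(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, datetime):
        return value.isoformat()
    return str(value)


def record_to_row(record: EMSRecord) -> dict[str, str]:
    """Flatten one record into a CSV row of strings."""
    row: dict[str, str] = {
        "record_id": record.record_id,
        "patient_key": record.patient_key,
        "patient_age": str(record.patient_age),
        "patient_sex": record.patient_sex.value,
        "dispatch_priority": str(record.dispatch_priority),
        "mission_type": record.mission_type.value,
        "mission_start": record.mission_start.isoformat(),
        "on_scene_arrival": _fmt_opt(record.on_scene_arrival),
        "scene_departure": _fmt_opt(record.scene_departure),
        "triage_colour": record.triage_colour.value,
        "chief_complaint": record.chief_complaint,
        "examinations": ";".join(sorted(record.examinations)),
        "drugs": json.dumps(
            [d.model_dump(mode="json") for d in record.drugs], sort_keys=True
        ),
        "repeated_panels": json.dumps(
            [p.model_dump(mode="json") for p in record.vitals.repeated_panels],
            sort_keys=True,
        ),
        "documentation": json.dumps(record.documentation, sort_keys=True),
        "conveyed": _fmt_opt(record.conveyance.conveyed),
        "conveyance_mode": record.conveyance.mode.value,
        "destination": _fmt_opt(record.conveyance.destination),
        "destination_per_guideline": _fmt_opt(
            record.conveyance.destination_per_guideline
        ),
        "ed_physician_triage_colour": (
            record.ed_handover.physician_triage_colour.value
            if record.ed_handover and record.ed_handover.physician_triage_colour
            else ""
        ),
        "ed_direct_to_definitive_care": (
            _fmt_opt(record.ed_handover.direct_to_definitive_care)
            if record.ed_handover
            else ""
        ),
        "ed_definitive_care_type": (
            record.ed_handover.definitive_care_type.value
            if record.ed_handover
            else ""
        ),
        "deterioration_noted": _fmt_opt(record.deterioration_noted),
        "manual_triggers": ";".join(sorted(record.manual_triggers)),
    }
    for v in _VITAL_FIELDS:
        row[f"vital_{v}"] = _fmt_opt(getattr(record.vitals, v))
    for s in SXABCDE_STEPS:
        row[f"sxabcde_{s}"] = record.sxabcde_steps[s].value
    for f in _FLAG_FIELDS:
        row[f"flag_{f}"] = _fmt_opt(getattr(record.environment_flags, f))
    return row


def _parse_bool(text: str, *, field_name: str) -> Optional[bool]:
    if text == "":
        return None
    low = text.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no"}:
        return False
    raise ValueError(f"{field_name}: cannot interpret {text!r} as boolean")


def row_to_record(row: Mapping[str, str]) -> EMSRecord:
    """Rebuild one record from a flattened CSV row (inverse of
    :func:`record_to_row`); raises ``ValueError``/``ValidationError`` on
    malformed content."""
    payload: dict[str, Any] = {
        "record_id": row["record_id"],
        "patient_key": row.get("patient_key", ""),
        "patient_age": row["patient_age"],
        "patient_sex": row["patient_sex"],
        "dispatch_priority": row["dispatch_priority"],
        "mission_type": row.get("mission_type", "primary_with_assessment"),
        "mission_start": row["mission_start"],
        "on_scene_arrival": row.get("on_scene_arrival") or None,
        "scene_departure": row.get("scene_departure") or None,
        "triage_colour": row.get("triage_colour") or "missing",
        "chief_complaint": row.get("chief_complaint") or "other",
        "deterioration_noted": _parse_bool(
            row.get("deterioration_noted", "false"), field_name="deterioration_noted"
        )
        or False,
    }
    vitals: dict[str, Any] = {}
    for v in _VITAL_FIELDS:
        cell = row.get(f"vital_{v}", "")
        if cell != "":
            vitals[v] = float(cell)
    vitals["repeated_panels"] = json.loads(row.get("repeated_panels", "") or "[]")
    payload["vitals"] = vitals
    payload["examinations"] = {
        e for e in (row.get("examinations", "") or "").split(";") if e
    }
    payload["manual_triggers"] = {
        e for e in (row.get("manual_triggers", "") or "").split(";") if e
    }
    payload["sxabcde_steps"] = {
        s: row.get(f"sxabcde_{s}", "assessed_and_addressed") for s in SXABCDE_STEPS
    }
    payload["drugs"] = json.loads(row.get("drugs", "") or "[]")
    payload["documentation"] = json.loads(row.get("documentation", "") or "{}")
    payload["environment_flags"] = {
        f: _parse_bool(row.get(f"flag_{f}", "false"), field_name=f"flag_{f}") or False
        for f in _FLAG_FIELDS
    }
    payload["conveyance"] = {
        "conveyed": _parse_bool(row.get("conveyed", ""), field_name="conveyed"),
        "mode": row.get("conveyance_mode") or "none",
        "destination": row.get("destination") or None,
        "destination_per_guideline": _parse_bool(
            row.get("destination_per_guideline", ""),
            field_name="destination_per_guideline",
        ),
    }
    if row.get("ed_definitive_care_type"):
        payload["ed_handover"] = {
            "physician_triage_colour": row.get("ed_physician_triage_colour") or None,
            "direct_to_definitive_care": _parse_bool(
                row.get("ed_direct_to_definitive_care", "false"),
                field_name="ed_direct_to_definitive_care",
            )
            or False,
            "definitive_care_type": row["ed_definitive_care_type"],
        }
    return EMSRecord.model_validate(payload)


def _issue_from_validation_error(row_idx: int, exc: ValidationError) -> list[ParseIssue]:
    issues = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<record>"
        issues.append(ParseIssue(row=row_idx, field=loc, message=err["msg"]))
    return issues


def _check_vocabulary(
    record: EMSRecord, vocab: Vocabulary, row_idx: int
) -> list[ParseIssue]:
    issues: list[ParseIssue] = []
    if record.chief_complaint not in vocab.chief_complaints:
        issues.append(
            ParseIssue(row_idx, "chief_complaint",
                       f"unknown code {record.chief_complaint!r}")
        )
    for exam in record.examinations:
        if exam not in vocab.examinations:
            issues.append(
                ParseIssue(row_idx, "examinations", f"unknown code {exam!r}")
            )
    for name, (lo, hi) in vocab.physiologic_bounds.items():
        value = getattr(record.vitals, name, None)
        if value is not None and not (lo <= value <= hi):
            issues.append(
                ParseIssue(
                    row_idx, f"vitals.{name}",
                    f"value {value} outside physiologic bounds [{lo}, {hi}]",
                )
            )
    return issues


def parse_records(
    source: str | Path,
    vocab: Vocabulary | None = None,
    fmt: str | None = None,
) -> ParseResult:
    """Read records from a CSV or JSON file.

    Every row either yields a validated :class:`EMSRecord` or contributes
    :class:`ParseIssue` entries carrying the row number and field; nothing
    is silently coerced.  ``fmt`` is inferred from the suffix when omitted.
    """
    path = Path(source)
    vocab = vocab or Vocabulary.default()
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    result = ParseResult()
    if fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            payloads = json.load(fh)
        if not isinstance(payloads, list):
            result.errors.append(
                ParseIssue(0, "<file>", "JSON file must contain an array of records")
            )
            return result
        for idx, payload in enumerate(payloads, start=1):
            try:
                record = EMSRecord.model_validate(payload)
            except ValidationError as exc:
                result.errors.extend(_issue_from_validation_error(idx, exc))
                continue
            vocab_issues = _check_vocabulary(record, vocab, idx)
            if vocab_issues:
                result.errors.extend(vocab_issues)
            else:
                result.records.append(record)
        return result

    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            result.errors.append(ParseIssue(0, "<file>", "missing header row"))
            return result
        for idx, row in enumerate(reader, start=1):
            if not (row.get("record_id") or "").strip():
                result.errors.append(
                    ParseIssue(idx, "record_id", "missing mandatory identifier")
                )
                continue
            try:
                record = row_to_record(row)
            except ValidationError as exc:
                result.errors.extend(_issue_from_validation_error(idx, exc))
                continue
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                result.errors.append(ParseIssue(idx, "<row>", str(exc)))
                continue
            vocab_issues = _check_vocabulary(record, vocab, idx)
            if vocab_issues:
                result.errors.extend(vocab_issues)
            else:
                result.records.append(record)
    return result


def write_records(
    records: Sequence[EMSRecord], path: str | Path, fmt: str | None = None
) -> None:
    """Write records to CSV or JSON (inferred from suffix when omitted)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                [r.model_dump(mode="json") for r in records], fh, indent=1
            )
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for record in records:
            writer.writerow(record_to_row(record))


# ---------------------------------------------------------------------------
# Cohort-level operations


def apply_inclusion_criteria(record: EMSRecord) -> bool:
    """Review-inclusion predicate: adult patient on a primary mission where
    an assessment took place."""
    return (
        record.patient_age >= 18
        and record.mission_type is MissionType.primary_with_assessment
    )


def link_returns(
    records: Iterable[EMSRecord], window_hours: float = 72.0
) -> dict[str, bool]:
    """Flag non-conveyed missions followed by a new contact for the same
    patient within ``window_hours``.

    The window is half-open, measured from the index mission's start:
    a return at exactly the index start does not count, one at exactly
    72 h does.  Conveyed records map to ``False``.  Records without a
    patient key are excluded from linkage (logged) and absent from the map.
    """
    recs = list(records)
    window = timedelta(hours=window_hours)
    by_patient: dict[str, list[datetime]] = {}
    for r in recs:
        if not r.patient_key:
            continue
        by_patient.setdefault(r.patient_key, []).append(r.mission_start)
    out: dict[str, bool] = {}
    for r in recs:
        if not r.patient_key:
            logger.warning(
                "record %s has no patient_key; excluded from 72-h linkage",
                r.record_id,
            )
            continue
        if r.conveyance.conveyed:
            out[r.record_id] = False
            continue
        t0 = r.mission_start
        out[r.record_id] = any(
            t0 < t <= t0 + window for t in by_patient[r.patient_key]
        )
    return out
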