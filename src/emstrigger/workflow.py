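"""Two-stage incident review and NCC MERP → WHO classification.

After screening, records with positive triggers are reviewed.  A primary
reviewer (a registered nurse) decides whether the positive triggers
contributed to an incident, how many, and whether the patient was exposed
to a risk of harm.  Depending on the workflow version:

* ``original`` — the primary reviewer grades incidents AB, C or D on the
  NCC MERP severity index; C and D incidents go to a secondary reviewer
  (a physician), who decides whether harm occurred and grades harmful
  incidents E–I.
* ``revised`` — the primary reviewer grades only AB or C; any incident
  with a risk of harm is passed ungraded to the secondary reviewer, who
  grades AB/C/D when no harm occurred and E–I (with harm type and a
  1–4 preventability score) when it did.

The NCC MERP categories map onto the WHO incident classes:
none → no incident, AB → near miss, C/D → no-harm incident,
E–I → harmful incident.

Reviewer judgement is always an explicit input (a judgement table read
from CSV, or the synthetic reviewer in :mod:`emstrigger.synthetic`); the
engine never infers clinical judgement from the record.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .triggers import ScreeningResult
from .vocabulary import Preventability


class MerpCategory(str, enum.Enum):
    """NCC MERP severity index; A and B are fused as reported jointly."""

    AB = "AB"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    G = "G"
    H = "H"
    I = "I"  # noqa: E741 - the index's own letter


class WhoClass(str, enum.Enum):
    no_incident = "no_incident"
    near_miss = "near_miss"
    no_harm_incident = "no_harm_incident"
    harmful_incident = "harmful_incident"


class WorkflowVersion(str, enum.Enum):
    original = "original"
    revised = "revised"


#: severity order used to pick a record-level class when several incidents
#: occurred on the same mission
_MERP_ORDER = {c: i for i, c in enumerate(MerpCategory)}
WHO_SEVERITY = {
    WhoClass.no_incident: 0,
    WhoClass.near_miss: 1,
    WhoClass.no_harm_incident: 2,
    WhoClass.harmful_incident: 3,
}

HARM_CATEGORIES = frozenset(
    {MerpCategory.E, MerpCategory.F, MerpCategory.G, MerpCategory.H, MerpCategory.I}
)

PRIMARY_CATEGORIES = {
    WorkflowVersion.original: frozenset({MerpCategory.AB, MerpCategory.C, MerpCategory.D}),
    WorkflowVersion.revised: frozenset({MerpCategory.AB, MerpCategory.C}),
}


class JudgementError(ValueError):
    """Inconsistent or incomplete reviewer judgement input."""


def merp_to_who(category: Optional[MerpCategory]) -> WhoClass:
    """Map an NCC MERP category (or no incident) to its WHO class."""
    if category is None:
        return WhoClass.no_incident
    if category is MerpCategory.AB:
        return WhoClass.near_miss
    if category in (MerpCategory.C, MerpCategory.D):
        return WhoClass.no_harm_incident
    return WhoClass.harmful_incident


@dataclass(frozen=True)
class Judgement:
    """One reviewed incident (or the explicit absence of one) on a record.

    ``primary_category`` is the primary reviewer's grading where the
    workflow allows one; ``category`` is the final grading (equal to the
    primary's when no secondary review happened).
    """

    record_id: str
    incident_present: bool
    risk_of_harm: bool = False
    primary_category: Optional[MerpCategory] = None
    category: Optional[MerpCategory] = None
    harm_type: Optional[str] = None
    preventability: Optional[Preventability] = None
    linked_triggers: tuple[str, ...] = ()


@dataclass(frozen=True)
class PrimaryReview:
    record_id: str
    incident_present: bool
    affects_patient_with_risk_of_harm: bool
    category: Optional[MerpCategory]
    linked_triggers: tuple[str, ...]
    incident_count: int


@dataclass(frozen=True)
class SecondaryReview:
    record_id: str
    harmed: bool
    category: MerpCategory
    harm_type: Optional[str] = None
    preventability: Optional[Preventability] = None

    def __post_init__(self) -> None:
        if self.harmed and self.category not in HARM_CATEGORIES:
            raise JudgementError(
                f"harmed incident on {self.record_id} must be graded E-I"
            )
        if not self.harmed and self.category in HARM_CATEGORIES:
            raise JudgementError(
                f"non-harm incident on {self.record_id} cannot be graded E-I"
            )
        if self.harmed and self.preventability is None:
            raise JudgementError(
                f"harmed incident on {self.record_id} needs a preventability score"
            )


@dataclass(frozen=True)
class IncidentClassification:
    record_id: str
    final_category: Optional[MerpCategory]
    who_class: WhoClass
    source: str  # primary_only | secondary

    def __post_init__(self) -> None:
        if merp_to_who(self.final_category) is not self.who_class:
            raise JudgementError("who_class inconsistent with final_category")


def classify_primary(
    screening: ScreeningResult,
    judgements: Sequence[Judgement],
    version: WorkflowVersion = WorkflowVersion.revised,
) -> PrimaryReview:
    """Aggregate a record's incident judgements into the primary review.

    Validates that judged incidents only reference triggers that screened
    positive, and that any primary grading stays within the categories the
    workflow version allows the primary reviewer to assign.
    """
    version = WorkflowVersion(version)
    positive = set(screening.positive_ids)
    incidents = [j for j in judgements if j.incident_present]
    for j in incidents:
        bad = set(j.linked_triggers) - positive
        if bad:
            raise JudgementError(
                f"judgement on {screening.record_id} references triggers "
                f"{sorted(bad)} that are not positive in screening"
            )
    if not positive or not incidents:
        return PrimaryReview(
            record_id=screening.record_id,
            incident_present=False,
            affects_patient_with_risk_of_harm=False,
            category=None,
            linked_triggers=(),
            incident_count=0,
        )
    risk = any(j.risk_of_harm for j in incidents)
    allowed = PRIMARY_CATEGORIES[version]
    primary_graded: list[MerpCategory] = []
    for j in incidents:
        if version is WorkflowVersion.revised and j.risk_of_harm:
            # grading is left entirely to the secondary reviewer
            continue
        cat = j.primary_category or j.category
        if cat is None:
            raise JudgementError(
                f"incident on {screening.record_id} lacks a primary category"
            )
        if cat not in allowed:
            raise JudgementError(
                f"primary category {cat.value} not allowed in "
                f"{version.value} workflow"
            )
        primary_graded.append(cat)
    category = (
        max(primary_graded, key=_MERP_ORDER.__getitem__) if primary_graded else None
    )
    linked = tuple(
        sorted({t for j in incidents for t in j.linked_triggers})
    )
    return PrimaryReview(
        record_id=screening.record_id,
        incident_present=True,
        affects_patient_with_risk_of_harm=risk,
        category=category,
        linked_triggers=linked,
        incident_count=len(incidents),
    )


def requires_secondary_review(
    primary: PrimaryReview, version: WorkflowVersion = WorkflowVersion.revised
) -> bool:
    """Routing rule for the physician's secondary review."""
    version = WorkflowVersion(version)
    if not primary.incident_present:
        return False
    if version is WorkflowVersion.original:
        return primary.category in (MerpCategory.C, MerpCategory.D)
    return primary.affects_patient_with_risk_of_harm


def merge_reviews(
    primary: PrimaryReview, secondary: Optional[SecondaryReview] = None,
    version: WorkflowVersion = WorkflowVersion.revised,
) -> IncidentClassification:
    """Resolve the record's final NCC MERP category and WHO class."""
    needed = requires_secondary_review(primary, version)
    if needed and secondary is None:
        raise JudgementError(
            f"record {primary.record_id} requires a secondary review"
        )
    if secondary is not None:
        final = secondary.category
        source = "secondary"
    else:
        final = primary.category
        source = "primary_only"
    return IncidentClassification(
        record_id=primary.record_id,
        final_category=final,
        who_class=merp_to_who(final),
        source=source,
    )


@dataclass
class CohortClassification:
    classifications: list[IncidentClassification]
    primaries: list[PrimaryReview]
    secondaries: dict[str, SecondaryReview]
    incidents: list[Judgement] = field(default_factory=list)

    def who_counts(self) -> dict[WhoClass, int]:
        counts = {w: 0 for w in WhoClass}
        for c in self.classifications:
            counts[c.who_class] += 1
        return counts


def _secondary_from_judgements(
    record_id: str, incidents: Sequence[Judgement], version: WorkflowVersion
) -> Optional[SecondaryReview]:
    if version is WorkflowVersion.revised:
        routed = [j for j in incidents if j.risk_of_harm]
    else:
        routed = [
            j for j in incidents
            if (j.primary_category or j.category) in (MerpCategory.C, MerpCategory.D)
        ]
    if not routed:
        return None
    graded: list[Judgement] = []
    for j in routed:
        if j.category is None:
            raise JudgementError(
                f"incident on {record_id} routed to secondary review "
                "lacks a final category"
            )
        graded.append(j)
    worst = max(graded, key=lambda j: _MERP_ORDER[j.category])
    harmed = worst.category in HARM_CATEGORIES
    return SecondaryReview(
        record_id=record_id,
        harmed=harmed,
        category=worst.category,
        harm_type=worst.harm_type,
        preventability=worst.preventability,
    )


def classify_cohort(
    screenings: Sequence[ScreeningResult],
    judgements: Iterable[Judgement],
    version: WorkflowVersion = WorkflowVersion.revised,
) -> CohortClassification:
    """Run the two-stage review over a screened cohort.

    Every screened record receives exactly one classification; records
    with no positive triggers (or an explicit no-incident judgement)
    resolve to the WHO class "no incident".
    """
    version = WorkflowVersion(version)
    by_record: dict[str, list[Judgement]] = {}
    for j in judgements:
        by_record.setdefault(j.record_id, []).append(j)
    known = {s.record_id for s in screenings}
    unknown = set(by_record) - known
    if unknown:
        raise JudgementError(
            f"judgements reference unscreened records: {sorted(unknown)[:5]}"
        )
    out = CohortClassification([], [], {}, [])
    for screening in screenings:
        rows = by_record.get(screening.record_id, [])
        incidents = [j for j in rows if j.incident_present]
        primary = classify_primary(screening, rows, version)
        secondary = None
        if requires_secondary_review(primary, version):
            secondary = _secondary_from_judgements(
                screening.record_id, incidents, version
            )
            if secondary is not None:
                out.secondaries[screening.record_id] = secondary
        out.primaries.append(primary)
        out.classifications.append(merge_reviews(primary, secondary, version))
        out.incidents.extend(incidents)
    return out


# ---------------------------------------------------------------------------
# Judgement file I/O

_JUDGEMENT_COLUMNS = (
    "record_id",
    "incident_present",
    "risk_of_harm",
    "primary_category",
    "category",
    "harm_type",
    "preventability",
    "linked_triggers",
)


def write_judgements(judgements: Sequence[Judgement], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_JUDGEMENT_COLUMNS)
        writer.writeheader()
        for j in judgements:
            writer.writerow(
                {
                    "record_id": j.record_id,
                    "incident_present": "true" if j.incident_present else "false",
                    "risk_of_harm": "true" if j.risk_of_harm else "false",
                    "primary_category": j.primary_category.value
                    if j.primary_category else "",
                    "category": j.category.value if j.category else "",
                    "harm_type": j.harm_type or "",
                    "preventability": str(int(j.preventability))
                    if j.preventability else "",
                    "linked_triggers": ";".join(j.linked_triggers),
                }
            )


def read_judgements(path: str | Path) -> list[Judgement]:
    out: list[Judgement] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_JUDGEMENT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise JudgementError(
                f"judgement file lacks columns: {sorted(missing)}"
            )
        for idx, row in enumerate(reader, start=1):
            try:
                out.append(
                    Judgement(
                        record_id=row["record_id"],
                        incident_present=row["incident_present"].lower() == "true",
                        risk_of_harm=row["risk_of_harm"].lower() == "true",
                        primary_category=MerpCategory(row["primary_category"])
                        if row["primary_category"] else None,
                        category=MerpCategory(row["category"])
                        if row["category"] else None,
                        harm_type=row["harm_type"] or None,
                        preventability=Preventability(int(row["preventability"]))
                        if row["preventability"] else None,
                        linked_triggers=tuple(
                            t for t in row["linked_triggers"].split(";") if t
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise JudgementError(f"judgement row {idx}: {exc}") from exc
    return out
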