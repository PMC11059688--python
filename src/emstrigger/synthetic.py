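"""Synthetic EMS cohorts with a known ground truth.

Real ambulance journals are confidential, so the pipeline is exercised on
generated cohorts: every record is built field-by-field so that exactly the
*planted* trigger conditions fire and nothing else, and a
:class:`GroundTruthManifest` records, per record, the planted positives,
the planted incident (with its NCC MERP grade and WHO class) and the
planted 72-hour return.  Screening, classification and reporting can then
be checked against the manifest exactly.

Default prevalences, incident mix and demographics emulate a Swedish
national ambulance record review (900 reviewed missions, of which 9 fail
the adult/primary-mission inclusion criteria; non-conveyance in ~21 % of
missions; guideline-deviation subtriggers around 3-16 %; near misses in
~41 % of records).  Triggers are planted independently except for
structural couplings: the response-time trigger needs a priority-1
dispatch, the on-scene-time trigger a red triage, and the conveyance
triggers (non-conveyance vs. alternative transport / destination / ED
handover) are mutually constrained, so those are planted conditionally
within their eligible stratum at rates that keep the unconditional
prevalence equal to the specified one.

Two reviewer simulators complete the loop: :func:`simulate_judgements`
derives a deterministic judgement table from the manifest (a "perfect"
reviewer), and :func:`simulate_raters` perturbs the screening truth with
per-rater sensitivity/specificity for inter-rater-reliability experiments.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    CareDecision,
    DrugAdministration,
    EDHandover,
    EMSRecord,
    EnvironmentFlags,
    TimedPanel,
    VitalObservation,
    VitalSignsPanel,
)
from .triggers import ScreeningResult, Status
from .vocabulary import (
    CORE_VITALS,
    ConveyanceMode,
    DefinitiveCareType,
    MissionType,
    Preventability,
    Sex,
    SxabcdeStatus,
    SXABCDE_STEPS,
    TriageColour,
    Vocabulary,
)
from .workflow import Judgement, MerpCategory, WhoClass, WorkflowVersion, WHO_SEVERITY

# triggers planted as independent boolean flags
_FLAG_TRIGGERS = {
    "A4": "weather_affected_care",
    "A5": "equipment_failure",
    "A6": "resource_shortage",
    "B2": "physical_harm_in_transport",
    "L2": "drug_mixup",
    "L3": "drug_shortage",
}

B1_SUBTRIGGERS = ("B1A", "B1B", "B1C", "B1D")

#: Default unconditional prevalences (fractions of eligible records), from
#: the pooled frequencies of a 891-record national review.
DEFAULT_TRIGGER_PREVALENCE: dict[str, float] = {
    "A1": 128 / 891,
    "A2": 26 / 891,
    "A3": 19 / 891,
    "A4": 0.0,
    "A5": 6 / 891,
    "A6": 3 / 891,
    "A7": 0.0,
    "B1A": 96 / 891,
    "B1B": 24 / 891,
    "B1C": 70 / 891,
    "B1D": 144 / 891,
    "B2": 0.0,
    "B3": 1 / 891,
    "B4": 12 / 891,
    "B5": 8 / 891,
    "B6": 185 / 891,
    "B7": 32 / 891,
    "B8": 2 / 891,
    "L1": 2 / 891,
    "L2": 0.0,
    "L3": 0.0,
}

#: P(near miss | positive), P(no-harm | positive), P(harmful | positive)
#: per trigger; the remainder is "trigger positive but no incident".
DEFAULT_INCIDENT_MODEL: dict[str, tuple[float, float, float]] = {
    "A1": (118 / 128, 7 / 128, 0.0),
    "A2": (21 / 26, 1 / 26, 1 / 26),
    "A3": (16 / 19, 0.0, 0.0),
    "A5": (1.0, 0.0, 0.0),
    "A6": (1.0, 0.0, 0.0),
    "B1A": (84 / 96, 11 / 96, 1 / 96),
    "B1B": (16 / 24, 8 / 24, 0.0),
    "B1C": (60 / 70, 6 / 70, 0.0),
    "B1D": (131 / 144, 9 / 144, 0.0),
    "B3": (1.0, 0.0, 0.0),
    "B4": (10 / 12, 1 / 12, 0.0),
    "B5": (0.5, 0.5, 0.0),
    "B6": (102 / 185, 5 / 185, 1 / 185),
    "B6_RETURN_72H": (19 / 28, 4 / 28, 1 / 28),
    "B7": (13 / 32, 0.0, 0.0),
    "B8": (0.5, 0.5, 0.0),
    "L1": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class Demographics:
    sex_female: float = 461 / 891
    priority_probs: Mapping[int, float] = dc_field(
        default_factory=lambda: {1: 362 / 891, 2: 485 / 891, 3: 44 / 891}
    )
    triage_probs: Mapping[str, float] = dc_field(
        default_factory=lambda: {
            "red": 84 / 891,
            "orange": 273 / 891,
            "yellow": 310 / 891,
            "green": 159 / 891,
            "blue": 5 / 891,
            "missing": 60 / 891,
        }
    )
    complaint_probs: Mapping[str, float] = dc_field(
        default_factory=lambda: {
            "dyspnoea": 0.098,
            "chest_pain": 0.100,
            "abdominal_pain": 0.071,
            "head_trauma": 0.048,
            "infection": 0.068,
            "dizziness": 0.044,
            "loss_of_consciousness": 0.030,
            "seizure": 0.020,
            "other": 0.521,
        }
    )
    age_mean: float = 67.0
    age_sd: float = 18.0


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_records: int = 900
    n_ineligible: int = 9
    start: tuple[int, int] = (2022, 1)  # (year, month)
    n_months: int = 12
    seed: int = 0
    demographics: Demographics = dc_field(default_factory=Demographics)
    trigger_prevalence: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_TRIGGER_PREVALENCE)
    )
    incident_model: Mapping[str, tuple[float, float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_INCIDENT_MODEL)
    )
    return_rate_72h: float = 28 / 185
    #: share of no-harm incidents graded D (risk of harm, secondary review)
    #: rather than C
    no_harm_d_share: float = 4 / 33
    #: NCC MERP grades (and weights) used for harmful incidents
    harm_category_weights: Mapping[str, float] = dc_field(
        default_factory=lambda: {"E": 0.5, "G": 0.5}
    )
    #: rate of language barriers handled correctly (barrier + interpreter)
    language_barrier_negative_rate: float = 0.02
    #: share of records with a second, stable vitals panel during transport
    second_panel_rate: float = 0.5
    #: share of records given analgesia (guideline-conform paracetamol)
    analgesia_rate: float = 0.3

    def validate(self, vocab: Optional[Vocabulary] = None) -> None:
        vocab = vocab or Vocabulary.default()
        demo = self.demographics
        for name, p in self.trigger_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {name} outside [0, 1]")
        for name, probs in self.incident_model.items():
            if min(probs) < 0 or sum(probs) > 1.0 + 1e-9:
                raise ValueError(f"incident model for {name} is not a sub-probability")
        if not 0.0 <= self.return_rate_72h <= 1.0:
            raise ValueError("return_rate_72h outside [0, 1]")
        if self.n_ineligible > self.n_records:
            raise ValueError("n_ineligible exceeds n_records")
        p = self.trigger_prevalence
        couplings = {
            "A2": ("priority-1 dispatches", demo.priority_probs.get(1, 0.0)),
            "A3": ("red-triage records", demo.triage_probs.get("red", 0.0)),
            "B1B": (
                "chest-pain records",
                demo.complaint_probs.get("chest_pain", 0.0),
            ),
            "B1D": (
                "records with a complaint-specific examination requirement",
                sum(
                    prob
                    for c, prob in demo.complaint_probs.items()
                    if c in vocab.exam_map
                ),
            ),
        }
        for trigger, (what, share) in couplings.items():
            if p.get(trigger, 0.0) > share + 1e-12:
                raise ValueError(
                    f"infeasible spec: {trigger} prevalence {p[trigger]:.3f} "
                    f"exceeds the share of {what} ({share:.3f})"
                )
        conveyed_share = 1.0 - p.get("B6", 0.0)
        for trigger in ("B5", "B7", "B8"):
            if p.get(trigger, 0.0) > conveyed_share + 1e-12:
                raise ValueError(
                    f"infeasible spec: {trigger} prevalence exceeds the "
                    f"conveyed share ({conveyed_share:.3f})"
                )


@dataclass(frozen=True)
class PlantedIncident:
    trigger_id: str
    who_class: WhoClass
    merp: MerpCategory


@dataclass(frozen=True)
class RecordTruth:
    record_id: str
    role: str  # index | ineligible | return_contact
    planted: frozenset[str]
    incidents: tuple[PlantedIncident, ...]
    return_within_72h: bool
    who_class: WhoClass


@dataclass
class GroundTruthManifest:
    entries: dict[str, RecordTruth]

    def eligible_ids(self) -> list[str]:
        return [rid for rid, t in self.entries.items() if t.role == "index"]

    def planted_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.entries.values():
            if t.role != "index":
                continue
            for trig in t.planted:
                counts[trig] = counts.get(trig, 0) + 1
        return counts

    def who_counts(self) -> dict[WhoClass, int]:
        counts = {w: 0 for w in WhoClass}
        for t in self.entries.values():
            if t.role == "index":
                counts[t.who_class] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.entries.values():
            rows.append(
                {
                    "record_id": t.record_id,
                    "role": t.role,
                    "planted": ";".join(sorted(t.planted)),
                    "return_within_72h": t.return_within_72h,
                    "who_class": t.who_class.value,
                    "incidents": ";".join(
                        f"{i.trigger_id}:{i.merp.value}:{i.who_class.value}"
                        for i in t.incidents
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RaterModel:
    """A noisy reviewer of trigger cells: marks a truly positive cell
    positive with probability ``sensitivity`` and a truly negative cell
    negative with probability ``specificity``."""

    sensitivity: float = 1.0
    specificity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Record construction helpers


def _choice(rng: np.random.Generator, probs: Mapping, normalize: bool = True):
    keys = list(probs.keys())
    weights = np.asarray([probs[k] for k in keys], dtype=float)
    if normalize:
        weights = weights / weights.sum()
    return keys[int(rng.choice(len(keys), p=weights))]


def _month_start(month: tuple[int, int]) -> datetime:
    return datetime(month[0], month[1], 1)


def _stable_vitals(rng: np.random.Generator) -> dict[str, float]:
    return {
        "respiratory_rate": float(rng.integers(12, 21)),
        "oxygen_saturation": float(rng.integers(95, 101)),
        "systolic_bp": float(rng.integers(110, 161)),
        "diastolic_bp": float(rng.integers(60, 96)),
        "pulse": float(rng.integers(60, 101)),
        "temperature": round(36.2 + float(rng.random()) * 1.2, 1),
    }


def generate_cohort(
    spec: CohortSpec, vocab: Optional[Vocabulary] = None
) -> tuple[list[EMSRecord], GroundTruthManifest]:
    """Build a cohort and its ground-truth manifest.

    Returns ``spec.n_records`` reviewed records (``spec.n_ineligible`` of
    which violate the inclusion criteria) plus one linked return-contact
    record per planted 72-hour return (``mission_type=other``: a later
    care contact visible to linkage but outside the reviewed sample).
    Deterministic for a fixed spec and seed.
    """
    vocab = vocab or Vocabulary.default()
    spec.validate(vocab)
    rng = np.random.default_rng(spec.seed)
    demo = spec.demographics
    p = {k: float(v) for k, v in spec.trigger_prevalence.items()}

    p_prio1 = demo.priority_probs.get(1, 0.0)
    p_red = demo.triage_probs.get("red", 0.0)
    p_chest = demo.complaint_probs.get("chest_pain", 0.0)
    p_exam = sum(
        prob for c, prob in demo.complaint_probs.items() if c in vocab.exam_map
    )
    conveyed_share = 1.0 - p.get("B6", 0.0)

    months = []
    y, m = spec.start
    for _ in range(spec.n_months):
        months.append((y, m))
        m += 1
        if m > 12:
            m, y = 1, y + 1

    n_index = spec.n_records - spec.n_ineligible
    records: list[EMSRecord] = []
    contacts: list[EMSRecord] = []
    entries: dict[str, RecordTruth] = {}

    for i in range(spec.n_records):
        rid = f"R{i:05d}"
        pkey = f"P{i:05d}"
        ineligible = i >= n_index

        month = months[int(rng.integers(0, len(months)))]
        days = calendar.monthrange(*month)[1]
        start = _month_start(month) + timedelta(
            minutes=int(rng.integers(0, days * 24 * 60))
        )
        sex = Sex.female if rng.random() < demo.sex_female else Sex.male
        age = int(np.clip(round(rng.normal(demo.age_mean, demo.age_sd)), 18, 103))
        priority = int(_choice(rng, demo.priority_probs))
        triage = TriageColour(_choice(rng, demo.triage_probs))
        complaint = str(_choice(rng, demo.complaint_probs))

        planted: set[str] = set()
        if not ineligible:
            if rng.random() < p.get("A1", 0.0):
                planted.add("A1")
            if priority == 1 and p_prio1 > 0 and rng.random() < min(
                1.0, p.get("A2", 0.0) / p_prio1
            ):
                planted.add("A2")
            if triage is TriageColour.red and p_red > 0 and rng.random() < min(
                1.0, p.get("A3", 0.0) / p_red
            ):
                planted.add("A3")
            for trig in _FLAG_TRIGGERS:
                if rng.random() < p.get(trig, 0.0):
                    planted.add(trig)
            if rng.random() < p.get("A7", 0.0):
                planted.add("A7")
            if rng.random() < p.get("B1A", 0.0):
                planted.add("B1A")
            if complaint == "chest_pain" and p_chest > 0 and rng.random() < min(
                1.0, p.get("B1B", 0.0) / p_chest
            ):
                planted.add("B1B")
            if rng.random() < p.get("B1C", 0.0):
                planted.add("B1C")
            if complaint in vocab.exam_map and p_exam > 0 and rng.random() < min(
                1.0, p.get("B1D", 0.0) / p_exam
            ):
                planted.add("B1D")
            if planted & set(B1_SUBTRIGGERS):
                planted.add("B1")
            if rng.random() < p.get("B3", 0.0):
                planted.add("B3")
            if rng.random() < p.get("B4", 0.0):
                planted.add("B4")
            if rng.random() < p.get("B6", 0.0):
                planted.add("B6")
                if rng.random() < spec.return_rate_72h:
                    planted.add("B6_RETURN_72H")
            else:
                for trig in ("B5", "B7", "B8"):
                    if conveyed_share > 0 and rng.random() < min(
                        1.0, p.get(trig, 0.0) / conveyed_share
                    ):
                        planted.add(trig)
            if rng.random() < p.get("L1", 0.0):
                planted.add("L1")

        # --- timeline ----------------------------------------------------
        if priority == 1:
            response = int(rng.integers(21, 46)) if "A2" in planted \
                else int(rng.integers(5, 21))
        else:
            response = int(rng.integers(8, 41))
        if triage is TriageColour.red:
            on_site = int(rng.integers(11, 41)) if "A3" in planted \
                else int(rng.integers(4, 11))
        else:
            on_site = int(rng.integers(5, 36))
        arrival = start + timedelta(minutes=response)
        departure = arrival + timedelta(minutes=on_site)

        # --- vitals ------------------------------------------------------
        base = _stable_vitals(rng)
        glucose_indicated = complaint in vocab.glucose_indicated_complaints
        vitals: dict[str, object] = dict(base)
        if glucose_indicated:
            vitals["blood_glucose"] = round(4.2 + float(rng.random()) * 3.0, 1)
        if "B1C" in planted:
            candidates = list(CORE_VITALS) + (
                ["blood_glucose"] if glucose_indicated else []
            )
            k = int(rng.integers(1, 3))
            for name in rng.choice(candidates, size=min(k, len(candidates)),
                                   replace=False):
                vitals[str(name)] = None

        panels: list[TimedPanel] = []
        if "B3" in planted:
            first = _stable_vitals(rng)
            second = dict(first)
            second["oxygen_saturation"] = float(rng.integers(80, 89))
            panels = [
                TimedPanel(time=arrival, values=VitalObservation(**first)),
                TimedPanel(time=departure, values=VitalObservation(**second)),
            ]
        elif rng.random() < spec.second_panel_rate:
            obs = _stable_vitals(rng)
            panels = [
                TimedPanel(time=arrival, values=VitalObservation(**obs)),
                TimedPanel(time=departure, values=VitalObservation(**obs)),
            ]

        # --- assessments and interventions --------------------------------
        steps = {s: SxabcdeStatus.assessed_and_addressed for s in SXABCDE_STEPS}
        if "B1A" in planted:
            k = int(rng.integers(1, 3))
            for name in rng.choice(list(SXABCDE_STEPS), size=k, replace=False):
                steps[str(name)] = (
                    SxabcdeStatus.not_assessed
                    if rng.random() < 0.5
                    else SxabcdeStatus.assessed_not_addressed
                )

        exams = set(vocab.exam_map.get(complaint, ()))
        if "B1D" in planted and exams:
            k = int(rng.integers(1, len(exams) + 1))
            for name in rng.choice(sorted(exams), size=k, replace=False):
                exams.discard(str(name))

        drugs: list[DrugAdministration] = []
        if complaint == "chest_pain" and "B1B" not in planted:
            drugs.append(
                DrugAdministration(
                    drug_code="aspirin", dose=300.0, unit="mg", route="po",
                    indication="chest_pain", guideline_conform=True,
                )
            )
        if rng.random() < spec.analgesia_rate:
            drugs.append(
                DrugAdministration(
                    drug_code="paracetamol",
                    dose=float(rng.choice([500.0, 750.0, 1000.0])),
                    unit="mg", route="po", indication="pain",
                    guideline_conform=True,
                )
            )
        if "L1" in planted:
            drugs.append(
                DrugAdministration(
                    drug_code="morphine", dose=20.0, unit="mg", route="iv",
                    indication="pain", guideline_conform=True,
                )
            )

        # --- conveyance and handover --------------------------------------
        if "B6" in planted:
            conveyance = CareDecision(conveyed=False, mode=ConveyanceMode.none)
            handover = None
        else:
            if "B7" in planted:
                mode = ConveyanceMode(
                    _choice(
                        rng,
                        {
                            "patient_transport": 0.40,
                            "seated_transport": 0.32,
                            "own_transportation": 0.20,
                            "single_responder": 0.08,
                        },
                    )
                )
            else:
                mode = ConveyanceMode.ambulance
            conveyance = CareDecision(
                conveyed=True,
                mode=mode,
                destination="regional_ed",
                destination_per_guideline="B8" not in planted,
            )
            if "B5" in planted:
                handover = EDHandover(
                    physician_triage_colour=TriageColour.red,
                    direct_to_definitive_care=True,
                    definitive_care_type=DefinitiveCareType(
                        _choice(
                            rng,
                            {"thrombolysis": 1.0, "pci": 1.0, "intensive_care": 1.0},
                        )
                    ),
                )
            elif rng.random() < 0.8:
                handover = EDHandover(
                    physician_triage_colour=triage
                    if triage is not TriageColour.missing else None,
                    direct_to_definitive_care=False,
                    definitive_care_type=DefinitiveCareType.none,
                )
            else:
                handover = None

        flags = {name: (trig in planted) for trig, name in _FLAG_TRIGGERS.items()}
        if "B4" in planted:
            flags["language_barrier_present"] = True
            flags["interpreter_used"] = False
        elif rng.random() < spec.language_barrier_negative_rate:
            flags["language_barrier_present"] = True
            flags["interpreter_used"] = True
        else:
            flags["language_barrier_present"] = False
            flags["interpreter_used"] = False

        documentation = {c: True for c in vocab.a1_required_fields}
        if "A1" in planted:
            k = int(rng.integers(1, 3))
            for name in rng.choice(list(vocab.a1_required_fields), size=k,
                                   replace=False):
                documentation[str(name)] = False

        mission_type = MissionType.primary_with_assessment
        if ineligible:
            if rng.random() < 0.5:
                age = int(rng.integers(1, 18))
            else:
                mission_type = MissionType.other

        record = EMSRecord(
            record_id=rid,
            patient_key=pkey,
            patient_age=age,
            patient_sex=sex,
            dispatch_priority=priority,
            mission_start=start,
            on_scene_arrival=arrival,
            scene_departure=departure,
            triage_colour=triage,
            chief_complaint=complaint,
            vitals=VitalSignsPanel(
                **{k: v for k, v in vitals.items() if v is not None},
                repeated_panels=panels,
            ),
            examinations=exams,
            sxabcde_steps=steps,
            drugs=drugs,
            conveyance=conveyance,
            environment_flags=EnvironmentFlags(**flags),
            documentation=documentation,
            ed_handover=handover,
            mission_type=mission_type,
            manual_triggers={"A7"} if "A7" in planted else set(),
        )
        records.append(record)

        # --- planted incidents --------------------------------------------
        incidents: list[PlantedIncident] = []
        for trig in sorted(planted):
            model = spec.incident_model.get(trig)
            if model is None or trig == "B1":
                continue
            p_nm, p_nh, p_hi = model
            u = rng.random()
            if u < p_nm:
                incidents.append(
                    PlantedIncident(trig, WhoClass.near_miss, MerpCategory.AB)
                )
            elif u < p_nm + p_nh:
                merp = (
                    MerpCategory.D
                    if rng.random() < spec.no_harm_d_share
                    else MerpCategory.C
                )
                incidents.append(
                    PlantedIncident(trig, WhoClass.no_harm_incident, merp)
                )
            elif u < p_nm + p_nh + p_hi:
                merp = MerpCategory(_choice(rng, dict(spec.harm_category_weights)))
                incidents.append(
                    PlantedIncident(trig, WhoClass.harmful_incident, merp)
                )
        who = WhoClass.no_incident
        for inc in incidents:
            if WHO_SEVERITY[inc.who_class] > WHO_SEVERITY[who]:
                who = inc.who_class

        return_flag = "B6_RETURN_72H" in planted
        entries[rid] = RecordTruth(
            record_id=rid,
            role="ineligible" if ineligible else "index",
            planted=frozenset(planted),
            incidents=tuple(incidents),
            return_within_72h=return_flag,
            who_class=who if not ineligible else WhoClass.no_incident,
        )

        if return_flag:
            contact_id = f"{rid}-RC"
            contact_start = start + timedelta(
                hours=int(rng.integers(2, 71)), minutes=int(rng.integers(0, 60))
            )
            contact = EMSRecord(
                record_id=contact_id,
                patient_key=pkey,
                patient_age=age,
                patient_sex=sex,
                dispatch_priority=2,
                mission_start=contact_start,
                on_scene_arrival=contact_start + timedelta(minutes=15),
                scene_departure=contact_start + timedelta(minutes=30),
                triage_colour=TriageColour.yellow,
                chief_complaint=complaint,
                vitals=VitalSignsPanel(**_stable_vitals(rng)),
                examinations=set(vocab.exam_map.get(complaint, ())),
                conveyance=CareDecision(
                    conveyed=True,
                    mode=ConveyanceMode.ambulance,
                    destination="regional_ed",
                    destination_per_guideline=True,
                ),
                documentation={c: True for c in vocab.a1_required_fields},
                mission_type=MissionType.other,
            )
            contacts.append(contact)
            entries[contact_id] = RecordTruth(
                record_id=contact_id,
                role="return_contact",
                planted=frozenset(),
                incidents=(),
                return_within_72h=False,
                who_class=WhoClass.no_incident,
            )

    return records + contacts, GroundTruthManifest(entries=entries)


# ---------------------------------------------------------------------------
# Reviewer simulators


def screening_grid(screenings: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Records x triggers boolean grid (positive = True) from screenings."""
    trigger_ids = [r.trigger_id for r in screenings[0].results] if screenings else []
    data = {
        s.record_id: [r.status is Status.positive for r in s.results]
        for s in screenings
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=trigger_ids
    ).astype(bool)


def simulate_raters(
    truth: pd.DataFrame, model1: RaterModel, model2: RaterModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Perturb a truth grid independently per rater and per cell."""

    def rate(model: RaterModel) -> pd.DataFrame:
        rng = np.random.default_rng(model.seed)
        u = rng.random(truth.shape)
        marked = np.where(
            truth.to_numpy(), u < model.sensitivity, u >= model.specificity
        )
        return pd.DataFrame(marked, index=truth.index, columns=truth.columns)

    return rate(model1), rate(model2)


_DEFAULT_HARM_TYPE = "delayed_definitive_care"


def simulate_judgements(
    manifest: GroundTruthManifest,
    version: WorkflowVersion = WorkflowVersion.revised,
) -> list[Judgement]:
    """Deterministic "perfect reviewer": judgement rows that, run through
    the review workflow, reproduce the manifest's planted incident classes
    exactly.  Incidents on a guideline-deviation subtrigger are linked to
    both the subtrigger and the B1 aggregate, mirroring how reviewers tally
    them under the parent trigger as well."""
    version = WorkflowVersion(version)
    rows: list[Judgement] = []
    for truth in manifest.entries.values():
        if truth.role != "index":
            continue
        if not truth.incidents:
            rows.append(Judgement(record_id=truth.record_id, incident_present=False))
            continue
        for inc in truth.incidents:
            linked = (inc.trigger_id,)
            if inc.trigger_id in B1_SUBTRIGGERS:
                linked = (inc.trigger_id, "B1")
            harmful = inc.who_class is WhoClass.harmful_incident
            risk = harmful or inc.merp is MerpCategory.D
            if version is WorkflowVersion.revised:
                primary = None if risk else inc.merp
            else:
                primary = (
                    MerpCategory.C if harmful else inc.merp
                )
            rows.append(
                Judgement(
                    record_id=truth.record_id,
                    incident_present=True,
                    risk_of_harm=risk,
                    primary_category=primary,
                    category=inc.merp,
                    harm_type=_DEFAULT_HARM_TYPE if harmful else None,
                    preventability=Preventability.probably_preventable
                    if harmful else None,
                    linked_triggers=linked,
                )
            )
    return rows
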