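"""Controlled vocabulary for ambulance mission records.

Swedish EMS organizations document missions against region-specific code
lists (triage per RETTS-A, dispatch priorities 1-3, coded chief complaints
and examinations).  Everything that varies by region — code lists,
physiologic bounds, the documentation criteria behind the "incomplete
documentation" trigger, and the chief-complaint → required-examination map
— lives in a :class:`Vocabulary` object that can be loaded from YAML, so
the trigger rules themselves stay region-agnostic.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, Field, field_validator


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class TriageColour(str, enum.Enum):
    """RETTS-A acuity colours, highest (red) to lowest (blue)."""

    red = "red"
    orange = "orange"
    yellow = "yellow"
    green = "green"
    blue = "blue"
    missing = "missing"


class ConveyanceMode(str, enum.Enum):
    ambulance = "ambulance"
    patient_transport = "patient_transport"
    seated_transport = "seated_transport"
    single_responder = "single_responder"
    own_transportation = "own_transportation"
    none = "none"


#: Transport modes other than a regular ambulance that still convey the
#: patient — these fire the alternative-transport trigger (B7).
ALTERNATIVE_MODES = frozenset(
    {
        ConveyanceMode.patient_transport,
        ConveyanceMode.seated_transport,
        ConveyanceMode.single_responder,
        ConveyanceMode.own_transportation,
    }
)


class MissionType(str, enum.Enum):
    primary_with_assessment = "primary_with_assessment"
    other = "other"


class SxabcdeStatus(str, enum.Enum):
    assessed_and_addressed = "assessed_and_addressed"
    assessed_not_addressed = "assessed_not_addressed"
    not_assessed = "not_assessed"


class DefinitiveCareType(str, enum.Enum):
    thrombolysis = "thrombolysis"
    pci = "pci"
    intensive_care = "intensive_care"
    none = "none"


class Preventability(enum.IntEnum):
    not_preventable = 1
    probably_not_preventable = 2
    probably_preventable = 3
    certainly_preventable = 4


#: SX-ABCDE algorithm steps: Scene safety, eXsanguinating bleeding, Airway,
#: Breathing, Circulation, Disability, Exposure.
SXABCDE_STEPS = ("scene_safety", "X", "A", "B", "C", "D", "E")

#: The five core vital signs every assessed patient should have documented.
CORE_VITALS = (
    "respiratory_rate",
    "oxygen_saturation",
    "systolic_bp",
    "pulse",
    "temperature",
)

#: Chief complaints for which an absent blood glucose counts as a missing
#: vital sign.
GLUCOSE_INDICATED_COMPLAINTS = frozenset({"loss_of_consciousness", "seizure"})

ENVIRONMENT_FLAG_NAMES = (
    "weather_affected_care",
    "equipment_failure",
    "resource_shortage",
    "physical_harm_in_transport",
    "drug_mixup",
    "drug_shortage",
    "language_barrier_present",
    "interpreter_used",
)

DEFAULT_CHIEF_COMPLAINTS = (
    "chest_pain",
    "abdominal_pain",
    "dyspnoea",
    "head_trauma",
    "infection",
    "dizziness",
    "loss_of_consciousness",
    "seizure",
    "other",
)

DEFAULT_EXAMINATIONS = (
    "ecg",
    "abdominal_palpation",
    "abdominal_auscultation",
    "lung_auscultation",
    "neurological_exam",
)

#: Default documentation criteria behind the incomplete-documentation
#: trigger (A1).  Regional journal systems differ; these five are a
#: reconstruction and fully overridable through the vocabulary file.
DEFAULT_A1_CRITERIA = (
    "chief_complaint_documented",
    "vital_signs_documented",
    "triage_outcome_documented",
    "interventions_documented",
    "conveyance_decision_documented",
)

DEFAULT_EXAM_MAP: dict[str, tuple[str, ...]] = {
    "chest_pain": ("ecg",),
    "abdominal_pain": ("abdominal_palpation", "abdominal_auscultation"),
    "dyspnoea": ("lung_auscultation",),
    "head_trauma": ("neurological_exam",),
    "dizziness": ("neurological_exam",),
    "loss_of_consciousness": ("ecg", "neurological_exam"),
    "seizure": ("neurological_exam",),
}

#: Hard physiologic bounds used for record validation (not triage).
DEFAULT_PHYSIOLOGIC_BOUNDS: dict[str, tuple[float, float]] = {
    "respiratory_rate": (0.0, 80.0),
    "oxygen_saturation": (0.0, 100.0),
    "systolic_bp": (0.0, 320.0),
    "diastolic_bp": (0.0, 220.0),
    "pulse": (0.0, 300.0),
    "temperature": (20.0, 45.0),
    "blood_glucose": (0.0, 60.0),
}

#: RETTS-A "red" bounds used by the deterioration trigger (B3): a vital
#: that starts inside its bound and ends outside it during transport counts
#: as deterioration.  (lo, hi) = non-red range.
DEFAULT_RETTS_RED_BOUNDS: dict[str, tuple[float, float]] = {
    "respiratory_rate": (8.0, 30.0),
    "oxygen_saturation": (90.0, 101.0),
    "systolic_bp": (90.0, 321.0),
    "pulse": (40.0, 130.0),
    "temperature": (34.0, 41.0),
}


class Vocabulary(BaseModel):
    """Versioned code lists and bounds for one EMS organization."""

    version: str = "default-1"
    chief_complaints: tuple[str, ...] = DEFAULT_CHIEF_COMPLAINTS
    examinations: tuple[str, ...] = DEFAULT_EXAMINATIONS
    a1_required_fields: tuple[str, ...] = DEFAULT_A1_CRITERIA
    exam_map: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: dict(DEFAULT_EXAM_MAP)
    )
    physiologic_bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_PHYSIOLOGIC_BOUNDS)
    )
    retts_red_bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_RETTS_RED_BOUNDS)
    )
    #: complaints for which an absent blood glucose is a missing vital
    glucose_indicated_complaints: tuple[str, ...] = tuple(
        sorted(GLUCOSE_INDICATED_COMPLAINTS)
    )

    @field_validator("a1_required_fields")
    @classmethod
    def _non_empty_criteria(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("a1_required_fields must not be empty")
        return v

    @field_validator("exam_map")
    @classmethod
    def _non_empty_exam_sets(
        cls, v: Mapping[str, tuple[str, ...]]
    ) -> dict[str, tuple[str, ...]]:
        for complaint, exams in v.items():
            if not exams:
                raise ValueError(f"exam_map entry for {complaint!r} is empty")
        return dict(v)

    @classmethod
    def default(cls) -> "Vocabulary":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Vocabulary":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
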