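from datetime import datetime, timedelta

import pytest

from emstrigger import (
    CareDecision,
    DrugAdministration,
    EDHandover,
    EMSRecord,
    ScreeningContext,
    TriggerRegistry,
    VitalSignsPanel,
    Vocabulary,
    load_registry,
)
from emstrigger.vocabulary import ConveyanceMode, Sex, TriageColour

T0 = datetime(2022, 3, 10, 9, 0)


def make_record(**overrides) -> EMSRecord:
    """A fully documented, guideline-conform conveyed mission: every trigger
    evaluates negative or not-applicable on it."""
    vocab = Vocabulary.default()
    fields = dict(
        record_id="R1",
        patient_key="P1",
        patient_age=54,
        patient_sex=Sex.female,
        dispatch_priority=2,
        mission_start=T0,
        on_scene_arrival=T0 + timedelta(minutes=12),
        scene_departure=T0 + timedelta(minutes=30),
        triage_colour=TriageColour.yellow,
        chief_complaint="chest_pain",
        vitals=VitalSignsPanel(
            respiratory_rate=16,
            oxygen_saturation=97,
            systolic_bp=135,
            diastolic_bp=80,
            pulse=78,
            temperature=36.8,
        ),
        examinations={"ecg"},
        drugs=[
            DrugAdministration(
                drug_code="aspirin", dose=300, unit="mg", route="po",
                indication="chest_pain", guideline_conform=True,
            )
        ],
        conveyance=CareDecision(
            conveyed=True,
            mode=ConveyanceMode.ambulance,
            destination="regional_ed",
            destination_per_guideline=True,
        ),
        documentation={c: True for c in vocab.a1_required_fields},
        ed_handover=EDHandover(direct_to_definitive_care=False),
    )
    fields.update(overrides)
    return EMSRecord(**fields)


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary.default()


@pytest.fixture(scope="session")
def registry() -> TriggerRegistry:
    return load_registry("rrr900")


@pytest.fixture()
def ctx(vocab) -> ScreeningContext:
    return ScreeningContext(vocab=vocab, returns_map={"R1": False})
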