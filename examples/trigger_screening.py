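"""Screen a single ambulance mission record against the trigger registry.

Builds one mission: a priority-1 dispatch that took 27 minutes to reach a
chest-pain patient, where no ECG was taken and the temperature was never
measured.  Three conditions should fire: the response-time trigger (A2),
absent vital signs (B1C) and absent relevant examination (B1D) — and the
guideline-deviation aggregate (B1) fires because its subtriggers do.
"""

from datetime import datetime, timedelta

from emstrigger import (
    ScreeningContext,
    Status,
    load_registry,
    screen_record,
)
from emstrigger.records import (
    CareDecision,
    DrugAdministration,
    EMSRecord,
    VitalSignsPanel,
)
from emstrigger.vocabulary import ConveyanceMode, Sex, TriageColour

t0 = datetime(2022, 5, 4, 14, 5)
record = EMSRecord(
    record_id="M-1042",
    patient_key="P-77",
    patient_age=67,
    patient_sex=Sex.male,
    dispatch_priority=1,
    mission_start=t0,
    on_scene_arrival=t0 + timedelta(minutes=27),   # > 20 min on lights and sirens
    scene_departure=t0 + timedelta(minutes=42),
    triage_colour=TriageColour.orange,
    chief_complaint="chest_pain",
    vitals=VitalSignsPanel(                         # temperature missing
        respiratory_rate=18, oxygen_saturation=95,
        systolic_bp=150, pulse=92,
    ),
    examinations=set(),                             # no ECG for chest pain
    drugs=[DrugAdministration(drug_code="aspirin", dose=300, unit="mg",
                              indication="chest_pain", guideline_conform=True)],
    conveyance=CareDecision(conveyed=True, mode=ConveyanceMode.ambulance,
                            destination="regional_ed",
                            destination_per_guideline=True),
    documentation={
        "chief_complaint_documented": True,
        "vital_signs_documented": True,
        "triage_outcome_documented": True,
        "interventions_documented": True,
        "conveyance_decision_documented": True,
    },
)

registry = load_registry("rrr900")
ctx = ScreeningContext(returns_map={"M-1042": False})
screening = screen_record(record, registry, ctx)

print(f"record {screening.record_id}: {screening.positive_count} positive trigger(s)")
for result in screening.results:
    if result.status is Status.positive:
        evidence = ", ".join(f"{e.criterion}={e.observed}" for e in result.evidence)
        print(f"  {result.trigger_id}: {evidence}")
print()
print("Each positive trigger is a clue for the reviewing nurse, not yet an")
print("incident: the two-stage review decides whether harm occurred.")
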