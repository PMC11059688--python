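# Ambulance trigger tool registry — revised profile following the 900-record
# retrospective record review, revised after the closing consensus session:
# the free-form 'Other' trigger is retired (it never fired and rated lowest
# on utility).  Rule parameters reference the declarative
# predicate grammar documented in emstrigger.rules.  Condition rules and
# formulary content reconstruct regional guideline material and are meant
# to be overridden per organization.
profile: final
triggers:
  - id: A1
    title: Incomplete documentation
    group: A_general
    kind: documentation
  - id: A2
    title: Response time >20 min priority 1 (lights and sirens)
    group: A_general
    kind: response_time
    params: {threshold_min: 20, priority: 1}
  - id: A3
    title: Time on site >10 min in case of life-threatening conditions
    group: A_general
    kind: on_site_time
    params:
      threshold_min: 10
      life_threatening: {field: triage_colour, op: eq, value: red}
  - id: A4
    title: Weather and environment affect patient care
    group: A_general
    kind: flag_rule
    params:
      rule: {field: environment_flags.weather_affected_care, op: is_true}
  - id: A5
    title: Breakdown or faulty/missing equipment
    group: A_general
    kind: flag_rule
    params:
      rule: {field: environment_flags.equipment_failure, op: is_true}
  - id: A6
    title: Shortage of ambulance resources
    group: A_general
    kind: flag_rule
    params:
      rule: {field: environment_flags.resource_shortage, op: is_true}
  - id: A7
    title: Other
    group: A_general
    kind: manual
    active: false
  - id: B1A
    title: Assessment/Interventions according to SX-ABCDE
    group: B_care_process
    kind: sxabcde
  - id: B1B
    title: Assessment/Interventions in specific conditions
    group: B_care_process
    kind: condition_rules
    params:
      rules:
        - id: chest_pain_aspirin
          when: {field: chief_complaint, op: eq, value: chest_pain}
          require: {field: drug_codes, op: contains, value: aspirin}
        - id: hypoglycaemia_glucose
          when:
            all:
              - {field: chief_complaint, op: eq, value: loss_of_consciousness}
              - {field: vitals.blood_glucose, op: lt, value: 4.0}
          require: {field: drug_codes, op: contains, value: glucose}
  - id: B1C
    title: Absence of measured vital signs
    group: B_care_process
    kind: absent_vitals
  - id: B1D
    title: Absence of relevant clinical examination
    group: B_care_process
    kind: absent_examination
  - id: B1
    title: Deviations from treatment guidelines
    group: B_care_process
    kind: aggregate_any
    params: {members: [B1A, B1B, B1C, B1D]}
  - id: B2
    title: Physical harm during patient transport
    group: B_care_process
    kind: flag_rule
    params:
      rule: {field: environment_flags.physical_harm_in_transport, op: is_true}
  - id: B3
    title: Deterioration of patient's condition during transport
    group: B_care_process
    kind: deterioration
  - id: B4
    title: Telephone interpreter has not been used in case of language deficiency
    group: B_care_process
    kind: interpreter
  - id: B5
    title: Inconsistency between the EMS clinician's and emergency physician's assessment and triage
    group: B_care_process
    kind: ed_triage_inconsistency
  - id: B6
    title: The patient is non-conveyed after EMS assessment
    group: B_care_process
    kind: nonconveyance
  - id: B6_RETURN_72H
    title: Patient return within 72 h
    group: B_care_process
    kind: return_within_window
    params: {parent: B6}
  - id: B7
    title: Alternative mode of transport to definitive care
    group: B_care_process
    kind: alternative_transport
  - id: B8
    title: Ambulance destination deviates from local guidelines
    group: B_care_process
    kind: destination_deviation
  - id: L1
    title: Unfavourable/inappropriate drug treatment
    group: L_medication
    kind: formulary
    params:
      formulary:
        aspirin: {max_dose: 500, unit: mg, indications: [chest_pain]}
        paracetamol: {max_dose: 1000, unit: mg, indications: [pain, fever]}
        morphine: {max_dose: 10, unit: mg, indications: [pain, chest_pain]}
        glucose: {max_dose: 30, unit: g, indications: [hypoglycaemia]}
        ondansetron: {max_dose: 8, unit: mg, indications: [nausea]}
  - id: L2
    title: Mix-up of drugs
    group: L_medication
    kind: flag_rule
    params:
      rule: {field: environment_flags.drug_mixup, op: is_true}
  - id: L3
    title: Shortage of medicines due to absence/expiry date
    group: L_medication
    kind: flag_rule
    params:
      rule: {field: environment_flags.drug_shortage, op: is_true}
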