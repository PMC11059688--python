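"""Trigger rule engine: per-trigger criteria, aggregation, determinism."""

from datetime import timedelta

import pytest
from hypothesis import given, settings, strategies as st

from emstrigger import (
    ConfigurationError,
    ScreeningContext,
    Status,
    Vocabulary,
    evaluate_trigger,
    screen_record,
)
from emstrigger.records import (
    CareDecision,
    DrugAdministration,
    EDHandover,
    EnvironmentFlags,
    TimedPanel,
    VitalObservation,
    VitalSignsPanel,
)
from emstrigger.vocabulary import (
    ConveyanceMode,
    DefinitiveCareType,
    SxabcdeStatus,
    SXABCDE_STEPS,
    TriageColour,
)

from conftest import T0, make_record


def one(registry, ctx, record, trigger_id, prior=None):
    return evaluate_trigger(record, registry[trigger_id], ctx, prior or {})


def minutes(n):
    return timedelta(minutes=n)


class TestTimeTriggers:
    @pytest.mark.parametrize(
        "priority, response_min, expected",
        [
            (1, 25, Status.positive),
            (1, 20, Status.negative),   # strict ">"
            (1, 21, Status.positive),
            (2, 25, Status.not_applicable),
        ],
    )
    def test_a2_response_time(self, registry, ctx, priority, response_min, expected):
        record = make_record(
            dispatch_priority=priority,
            on_scene_arrival=T0 + minutes(response_min),
            scene_departure=T0 + minutes(response_min + 10),
        )
        assert one(registry, ctx, record, "A2").status is expected

    def test_a2_missing_timestamp_not_applicable(self, registry, ctx):
        record = make_record(
            dispatch_priority=1, on_scene_arrival=None, scene_departure=None
        )
        assert one(registry, ctx, record, "A2").status is Status.not_applicable

    @pytest.mark.parametrize(
        "colour, on_site_min, expected",
        [
            (TriageColour.red, 15, Status.positive),
            (TriageColour.red, 10, Status.negative),  # strict ">"
            (TriageColour.yellow, 40, Status.not_applicable),
        ],
    )
    def test_a3_time_on_site_for_life_threatening(
        self, registry, ctx, colour, on_site_min, expected
    ):
        record = make_record(
            triage_colour=colour,
            on_scene_arrival=T0 + minutes(10),
            scene_departure=T0 + minutes(10 + on_site_min),
        )
        assert one(registry, ctx, record, "A3").status is expected


class TestFlagAndManualTriggers:
    @pytest.mark.parametrize(
        "trigger_id, flag",
        [
            ("A4", "weather_affected_care"),
            ("A5", "equipment_failure"),
            ("A6", "resource_shortage"),
            ("B2", "physical_harm_in_transport"),
            ("L2", "drug_mixup"),
            ("L3", "drug_shortage"),
        ],
    )
    def test_flag_triggers_follow_their_flag(self, registry, ctx, trigger_id, flag):
        on = make_record(environment_flags=EnvironmentFlags(**{flag: True}))
        off = make_record()
        assert one(registry, ctx, on, trigger_id).status is Status.positive
        assert one(registry, ctx, off, trigger_id).status is Status.negative

    def test_a7_only_fires_on_manual_annotation(self, registry, ctx):
        assert one(registry, ctx, make_record(), "A7").status is Status.negative
        annotated = make_record(manual_triggers={"A7"})
        assert one(registry, ctx, annotated, "A7").status is Status.positive


class TestDocumentationTrigger:
    def test_all_criteria_met_negative(self, registry, ctx):
        assert one(registry, ctx, make_record(), "A1").status is Status.negative

    def test_missing_vitals_criterion_named_in_evidence(self, registry, ctx, vocab):
        docs = {c: True for c in vocab.a1_required_fields}
        docs["vital_signs_documented"] = False
        result = one(registry, ctx, make_record(documentation=docs), "A1")
        assert result.status is Status.positive
        assert [e.criterion for e in result.evidence] == ["vital_signs_documented"]

    @given(
        missing=st.sets(
            st.sampled_from(list(Vocabulary.default().a1_required_fields))
        ),
        extra=st.sampled_from(list(Vocabulary.default().a1_required_fields)),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_missing_fields(self, missing, extra):
        """Removing one more documented field can never clear the trigger."""
        vocab = Vocabulary.default()
        ctx = ScreeningContext(vocab=vocab)
        from emstrigger import load_registry

        registry = load_registry()
        docs = {c: c not in missing for c in vocab.a1_required_fields}
        before = one(registry, ctx, make_record(documentation=docs), "A1").status
        docs[extra] = False
        after = one(registry, ctx, make_record(documentation=docs), "A1").status
        if before is Status.positive:
            assert after is Status.positive
        assert (before is Status.positive) == bool(missing)


class TestGuidelineDeviationSubtriggers:
    def test_b1a_flags_unassessed_or_unaddressed_steps(self, registry, ctx):
        steps = {s: SxabcdeStatus.assessed_and_addressed for s in SXABCDE_STEPS}
        assert one(registry, ctx, make_record(sxabcde_steps=dict(steps)), "B1A").status is Status.negative
        steps["B"] = SxabcdeStatus.not_assessed
        result = one(registry, ctx, make_record(sxabcde_steps=dict(steps)), "B1A")
        assert result.status is Status.positive
        assert result.evidence[0].criterion == "B"
        steps["B"] = SxabcdeStatus.assessed_and_addressed
        steps["scene_safety"] = SxabcdeStatus.assessed_not_addressed
        assert one(registry, ctx, make_record(sxabcde_steps=dict(steps)), "B1A").status is Status.positive

    def test_b1b_chest_pain_without_aspirin(self, registry, ctx):
        assert one(registry, ctx, make_record(), "B1B").status is Status.negative
        result = one(registry, ctx, make_record(drugs=[]), "B1B")
        assert result.status is Status.positive
        assert result.evidence[0].criterion == "chest_pain_aspirin"
        unmatched = make_record(chief_complaint="infection", examinations=set(), drugs=[])
        assert one(registry, ctx, unmatched, "B1B").status is Status.not_applicable

    @pytest.mark.parametrize(
        "complaint, drop, glucose, expected",
        [
            ("chest_pain", None, None, Status.negative),  # glucose not indicated
            ("seizure", None, None, Status.positive),     # indicated but absent
            ("seizure", None, 5.5, Status.negative),
            ("chest_pain", "temperature", None, Status.positive),
        ],
    )
    def test_b1c_absent_vitals(self, registry, ctx, complaint, drop, glucose, expected):
        panel = dict(
            respiratory_rate=16, oxygen_saturation=97, systolic_bp=130,
            pulse=75, temperature=36.9, blood_glucose=glucose,
        )
        if drop:
            panel[drop] = None
        record = make_record(
            chief_complaint=complaint,
            examinations=set() if complaint != "chest_pain" else {"ecg"},
            drugs=[] if complaint != "chest_pain" else make_record().drugs,
            vitals=VitalSignsPanel(**{k: v for k, v in panel.items() if v is not None}),
        )
        assert one(registry, ctx, record, "B1C").status is expected

    def test_b1d_missing_examination(self, registry, ctx):
        assert one(registry, ctx, make_record(), "B1D").status is Status.negative
        no_ecg = make_record(examinations=set())
        result = one(registry, ctx, no_ecg, "B1D")
        assert result.status is Status.positive
        assert result.evidence[0].criterion == "ecg"
        abdo = make_record(
            chief_complaint="abdominal_pain",
            examinations={"abdominal_palpation", "abdominal_auscultation"},
            drugs=[],
        )
        assert one(registry, ctx, abdo, "B1D").status is Status.negative
        unmapped = make_record(chief_complaint="infection", examinations=set(), drugs=[])
        assert one(registry, ctx, unmapped, "B1D").status is Status.not_applicable

    def test_b1_aggregate_matches_enumerated_oracle(self, registry, vocab):
        """Brute-force check over an enumerated record space: the aggregate
        equals the disjunction of its subtriggers in every cell."""
        ctx = ScreeningContext(vocab=vocab, returns_map={"R1": False})
        complaints = ["chest_pain", "infection"]
        space = [
            (complaint, a_bad, b_bad, c_bad, d_bad)
            for complaint in complaints
            for a_bad in (False, True)
            for b_bad in (False, True)
            for c_bad in (False, True)
            for d_bad in (False, True)
        ]
        for complaint, a_bad, b_bad, c_bad, d_bad in space:
            steps = {s: SxabcdeStatus.assessed_and_addressed for s in SXABCDE_STEPS}
            if a_bad:
                steps["C"] = SxabcdeStatus.not_assessed
            vitals = dict(respiratory_rate=14, oxygen_saturation=98,
                          systolic_bp=120, pulse=70, temperature=37.0)
            if c_bad:
                vitals.pop("pulse")
            exams = set(vocab.exam_map.get(complaint, ()))
            if d_bad:
                exams = set()
            drugs = []
            if complaint == "chest_pain" and not b_bad:
                drugs = make_record().drugs
            record = make_record(
                chief_complaint=complaint,
                sxabcde_steps=steps,
                vitals=VitalSignsPanel(**vitals),
                examinations=exams,
                drugs=drugs,
            )
            screening = screen_record(record, registry, ctx).by_id()
            # expected positivity from the enumeration itself
            expect = {
                "B1A": a_bad,
                "B1B": b_bad and complaint == "chest_pain",
                "B1C": c_bad,
                "B1D": d_bad and complaint in vocab.exam_map,
            }
            for sub, positive in expect.items():
                assert (screening[sub].status is Status.positive) == positive, (
                    complaint, sub, a_bad, b_bad, c_bad, d_bad
                )
            assert (screening["B1"].status is Status.positive) == any(expect.values())


class TestCareProcessTriggers:
    def test_b3_requires_two_panels(self, registry, ctx):
        assert one(registry, ctx, make_record(), "B3").status is Status.not_applicable

    def test_b3_saturation_crossing_red_bound(self, registry, ctx):
        stable = dict(respiratory_rate=15, oxygen_saturation=96,
                      systolic_bp=125, pulse=80, temperature=37.0)
        worse = dict(stable, oxygen_saturation=84.0)
        record = make_record(
            vitals=VitalSignsPanel(
                **stable,
                repeated_panels=[
                    TimedPanel(time=T0 + minutes(12), values=VitalObservation(**stable)),
                    TimedPanel(time=T0 + minutes(25), values=VitalObservation(**worse)),
                ],
            )
        )
        result = one(registry, ctx, record, "B3")
        assert result.status is Status.positive
        assert result.evidence[0].criterion == "oxygen_saturation"
        stable_record = make_record(
            vitals=VitalSignsPanel(
                **stable,
                repeated_panels=[
                    TimedPanel(time=T0 + minutes(12), values=VitalObservation(**stable)),
                    TimedPanel(time=T0 + minutes(25), values=VitalObservation(**stable)),
                ],
            )
        )
        assert one(registry, ctx, stable_record, "B3").status is Status.negative

    @pytest.mark.parametrize(
        "barrier, interpreter, expected",
        [
            (True, False, Status.positive),
            (True, True, Status.negative),
            (False, False, Status.not_applicable),
        ],
    )
    def test_b4_interpreter(self, registry, ctx, barrier, interpreter, expected):
        record = make_record(
            environment_flags=EnvironmentFlags(
                language_barrier_present=barrier, interpreter_used=interpreter
            )
        )
        assert one(registry, ctx, record, "B4").status is expected

    def test_b5_direct_to_definitive_care(self, registry, ctx):
        pci = make_record(
            ed_handover=EDHandover(
                direct_to_definitive_care=True,
                definitive_care_type=DefinitiveCareType.pci,
            )
        )
        assert one(registry, ctx, pci, "B5").status is Status.positive
        ward = make_record()  # handover without direct-to-definitive-care
        assert one(registry, ctx, ward, "B5").status is Status.negative
        nonconveyed = make_record(
            conveyance=CareDecision(conveyed=False, mode=ConveyanceMode.none),
            ed_handover=None,
        )
        assert one(registry, ctx, nonconveyed, "B5").status is Status.not_applicable

    def test_b6_and_return_subtrigger(self, registry, vocab):
        nonconveyed = make_record(
            conveyance=CareDecision(conveyed=False, mode=ConveyanceMode.none),
            ed_handover=None,
        )
        ctx = ScreeningContext(vocab=vocab, returns_map={"R1": True})
        screening = screen_record(nonconveyed, registry, ctx).by_id()
        assert screening["B6"].status is Status.positive
        assert screening["B6_RETURN_72H"].status is Status.positive
        ctx_no_return = ScreeningContext(vocab=vocab, returns_map={"R1": False})
        screening = screen_record(nonconveyed, registry, ctx_no_return).by_id()
        assert screening["B6_RETURN_72H"].status is Status.negative
        conveyed = make_record()
        screening = screen_record(conveyed, registry, ctx_no_return).by_id()
        assert screening["B6"].status is Status.negative
        assert screening["B6_RETURN_72H"].status is Status.not_applicable

    def test_b6_return_missing_from_map_is_config_error(self, registry, vocab):
        nonconveyed = make_record(
            conveyance=CareDecision(conveyed=False, mode=ConveyanceMode.none),
            ed_handover=None,
        )
        ctx = ScreeningContext(vocab=vocab, returns_map={})
        with pytest.raises(ConfigurationError, match="returns map"):
            screen_record(nonconveyed, registry, ctx)

    @pytest.mark.parametrize(
        "mode, expected",
        [
            (ConveyanceMode.ambulance, Status.negative),
            (ConveyanceMode.own_transportation, Status.positive),
            (ConveyanceMode.seated_transport, Status.positive),
        ],
    )
    def test_b7_alternative_transport(self, registry, ctx, mode, expected):
        record = make_record(
            conveyance=CareDecision(
                conveyed=True, mode=mode, destination="regional_ed",
                destination_per_guideline=True,
            )
        )
        assert one(registry, ctx, record, "B7").status is expected

    @pytest.mark.parametrize(
        "per_guideline, expected",
        [
            (False, Status.positive),
            (True, Status.negative),
            (None, Status.not_applicable),
        ],
    )
    def test_b8_destination(self, registry, ctx, per_guideline, expected):
        record = make_record(
            conveyance=CareDecision(
                conveyed=True, mode=ConveyanceMode.ambulance,
                destination="regional_ed", destination_per_guideline=per_guideline,
            )
        )
        assert one(registry, ctx, record, "B8").status is expected


class TestMedicationTrigger:
    def test_conform_drug_negative(self, registry, ctx):
        assert one(registry, ctx, make_record(), "L1").status is Status.negative

    def test_dose_above_maximum_positive(self, registry, ctx):
        record = make_record(
            drugs=[
                DrugAdministration(
                    drug_code="morphine", dose=20, unit="mg", route="iv",
                    indication="pain", guideline_conform=True,
                )
            ]
        )
        result = one(registry, ctx, record, "L1")
        assert result.status is Status.positive
        assert "above maximum" in result.evidence[0].observed

    def test_unlisted_indication_positive(self, registry, ctx):
        record = make_record(
            drugs=[
                DrugAdministration(
                    drug_code="ondansetron", dose=4, unit="mg", route="iv",
                    indication="chest_pain",
                )
            ]
        )
        assert one(registry, ctx, record, "L1").status is Status.positive

    def test_no_drugs_not_applicable(self, registry, ctx):
        record = make_record(chief_complaint="infection", examinations=set(), drugs=[])
        assert one(registry, ctx, record, "L1").status is Status.not_applicable

    def test_unknown_drug_not_evaluable_not_positive(self, registry, ctx):
        record = make_record(
            drugs=make_record().drugs
            + [DrugAdministration(drug_code="experimentalium", dose=1)]
        )
        assert one(registry, ctx, record, "L1").status is Status.negative


class TestScreening:
    def test_perfect_record_has_zero_positives(self, registry, ctx):
        screening = screen_record(make_record(), registry, ctx)
        assert screening.positive_count == 0
        assert all(
            r.status in (Status.negative, Status.not_applicable)
            for r in screening.results
        )

    def test_one_result_per_active_trigger(self, registry, ctx):
        screening = screen_record(make_record(), registry, ctx)
        assert len(screening.results) == len(registry.active())
        assert {r.trigger_id for r in screening.results} == {
            d.trigger_id for d in registry.active()
        }

    def test_forced_composition_counts_two_positives(self, registry, ctx, vocab):
        record = make_record(
            dispatch_priority=1,
            on_scene_arrival=T0 + minutes(25),
            scene_departure=T0 + minutes(40),
            vitals=VitalSignsPanel(
                respiratory_rate=16, oxygen_saturation=97, systolic_bp=130, pulse=75
            ),  # temperature absent -> B1C
        )
        screening = screen_record(record, registry, ctx)
        # A2 and B1C fire, and B1C lifts the B1 aggregate with it
        assert set(screening.positive_ids) == {"A2", "B1C", "B1"}

    def test_screening_is_deterministic(self, registry, ctx):
        record = make_record(drugs=[])
        assert screen_record(record, registry, ctx) == screen_record(
            record, registry, ctx
        )

    def test_final_profile_retires_the_manual_trigger(self, ctx):
        from emstrigger import load_registry

        final = load_registry("final")
        active_ids = {d.trigger_id for d in final.active()}
        assert "A7" not in active_ids
        assert len(active_ids) == 22
        screening = screen_record(make_record(), final, ctx)
        assert len(screening.results) == 22
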