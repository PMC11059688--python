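"""The ambulance trigger tool's rule engine.

Each trigger is a predefined clue that a patient-safety incident may have
occurred (for example "response time > 20 min on a lights-and-sirens
mission" or "a core vital sign was never measured").  A trigger applied to
one mission record yields one of three statuses:

* ``positive`` — the trigger's criteria are met; the record goes to review;
* ``negative`` — the criteria were evaluable and not met;
* ``not_applicable`` — the record is outside the trigger's scope (e.g. the
  response-time trigger on a non-urgent dispatch) or the data needed to
  evaluate it are absent.  Missing data never produce a positive.

The registry mirrors the national ambulance trigger tool: group A (general
care environment), group B (the care process, including the B1 guideline-
deviation subtriggers B1A–B1D and the 72-hour-return subtrigger of B6), and
group L (medication).  Two profiles ship with the package: ``rrr900`` (the
full set used during the 900-record review) and ``final`` (the revised set
with the free-form "other" trigger retired).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence

import yaml

from .records import EMSRecord, link_returns
from .rules import evaluate_rule, feature_view, minutes_between, rule_observations
from .vocabulary import (
    ALTERNATIVE_MODES,
    CORE_VITALS,
    DefinitiveCareType,
    SxabcdeStatus,
    SXABCDE_STEPS,
    TriageColour,
    Vocabulary,
)

logger = logging.getLogger(__name__)


class ConfigurationError(RuntimeError):
    """Raised when the registry or screening context is unusable."""


class Status(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    not_applicable = "not_applicable"


class TriggerGroup(str, enum.Enum):
    A_general = "A_general"
    B_care_process = "B_care_process"
    L_medication = "L_medication"


@dataclass(frozen=True)
class Evidence:
    criterion: str
    observed: Any


@dataclass(frozen=True)
class TriggerResult:
    trigger_id: str
    status: Status
    evidence: tuple[Evidence, ...]
    record_id: str

    def __post_init__(self) -> None:
        if self.status is Status.positive and not self.evidence:
            raise ValueError(
                f"positive result for {self.trigger_id} requires evidence"
            )


@dataclass(frozen=True)
class ScreeningResult:
    """All active-trigger outcomes for one record."""

    record_id: str
    results: tuple[TriggerResult, ...]

    @property
    def positive_count(self) -> int:
        return sum(1 for r in self.results if r.status is Status.positive)

    @property
    def positive_ids(self) -> tuple[str, ...]:
        return tuple(
            r.trigger_id for r in self.results if r.status is Status.positive
        )

    def by_id(self) -> dict[str, TriggerResult]:
        return {r.trigger_id: r for r in self.results}


@dataclass(frozen=True)
class TriggerDefinition:
    trigger_id: str
    title: str
    group: TriggerGroup
    kind: str
    active: bool = True
    params: Mapping[str, Any] = field(default_factory=dict)


class TriggerRegistry:
    """Ordered collection of trigger definitions for one profile."""

    def __init__(self, profile: str, definitions: Sequence[TriggerDefinition]):
        self.profile = profile
        self.definitions = tuple(definitions)
        ids = [d.trigger_id for d in self.definitions]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate trigger ids in registry")
        seen: set[str] = set()
        for d in self.definitions:
            for dep in _dependencies(d):
                if dep not in seen:
                    raise ConfigurationError(
                        f"trigger {d.trigger_id} depends on {dep} which is not "
                        "defined earlier in the registry"
                    )
            seen.add(d.trigger_id)
        unknown = {d.kind for d in self.definitions} - set(_EVALUATORS)
        if unknown:
            raise ConfigurationError(f"unknown trigger kinds: {sorted(unknown)}")

    def active(self) -> tuple[TriggerDefinition, ...]:
        return tuple(d for d in self.definitions if d.active)

    def __getitem__(self, trigger_id: str) -> TriggerDefinition:
        for d in self.definitions:
            if d.trigger_id == trigger_id:
                return d
        raise KeyError(trigger_id)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TriggerRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "TriggerRegistry":
        try:
            triggers = data["triggers"]
            defs = [
                TriggerDefinition(
                    trigger_id=t["id"],
                    title=t.get("title", t["id"]),
                    group=TriggerGroup(t["group"]),
                    kind=t["kind"],
                    active=bool(t.get("active", True)),
                    params=t.get("params", {}) or {},
                )
                for t in triggers
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid registry: {exc}") from exc
        return cls(profile=str(data.get("profile", "custom")), definitions=defs)


def load_registry(profile: str = "rrr900") -> TriggerRegistry:
    """Load one of the packaged registry profiles (``rrr900`` or ``final``)."""
    name = f"registry_{profile}.yaml"
    ref = resources.files("emstrigger.data").joinpath(name)
    if not ref.is_file():
        raise ConfigurationError(f"no packaged registry profile {profile!r}")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return TriggerRegistry.from_dict(data)


@dataclass
class ScreeningContext:
    """Everything the rule engine needs besides the record itself."""

    vocab: Vocabulary = field(default_factory=Vocabulary.default)
    returns_map: Mapping[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Evaluators (one per trigger kind)


def _result(
    defn: TriggerDefinition,
    record: EMSRecord,
    status: Status,
    evidence: Iterable[tuple[str, Any]] = (),
) -> TriggerResult:
    return TriggerResult(
        trigger_id=defn.trigger_id,
        status=status,
        evidence=tuple(Evidence(c, o) for c, o in evidence),
        record_id=record.record_id,
    )


def _eval_documentation(record, defn, ctx, prior):
    required = tuple(defn.params.get("required_fields") or ctx.vocab.a1_required_fields)
    if not required:
        raise ConfigurationError("documentation trigger needs required_fields")
    unmet = [f for f in required if not record.documentation.get(f, False)]
    if unmet:
        return _result(defn, record, Status.positive, [(f, "absent") for f in unmet])
    return _result(defn, record, Status.negative,
                   [("documentation", "all criteria met")])


def _eval_response_time(record, defn, ctx, prior):
    priority = int(defn.params.get("priority", 1))
    threshold = int(defn.params.get("threshold_min", 20))
    if record.dispatch_priority != priority:
        return _result(defn, record, Status.not_applicable)
    elapsed = minutes_between(record.mission_start, record.on_scene_arrival)
    if elapsed is None:
        return _result(defn, record, Status.not_applicable)
    if elapsed > threshold:
        return _result(defn, record, Status.positive,
                       [("response_time_min", elapsed)])
    return _result(defn, record, Status.negative, [("response_time_min", elapsed)])


def _eval_on_site_time(record, defn, ctx, prior):
    threshold = int(defn.params.get("threshold_min", 10))
    life_threatening_rule = defn.params.get(
        "life_threatening", {"field": "triage_colour", "op": "eq", "value": "red"}
    )
    if evaluate_rule(life_threatening_rule, feature_view(record)) is not True:
        return _result(defn, record, Status.not_applicable)
    elapsed = minutes_between(record.on_scene_arrival, record.scene_departure)
    if elapsed is None:
        return _result(defn, record, Status.not_applicable)
    if elapsed > threshold:
        return _result(defn, record, Status.positive, [("on_site_time_min", elapsed)])
    return _result(defn, record, Status.negative, [("on_site_time_min", elapsed)])


def _eval_flag_rule(record, defn, ctx, prior):
    rule = defn.params.get("rule")
    if not rule:
        raise ConfigurationError(
            f"flag trigger {defn.trigger_id} needs a 'rule' parameter"
        )
    view = feature_view(record)
    outcome = evaluate_rule(rule, view)
    if outcome is None:
        return _result(defn, record, Status.not_applicable)
    obs = rule_observations(rule, view)
    if outcome:
        return _result(defn, record, Status.positive, obs)
    return _result(defn, record, Status.negative, obs)


def _eval_manual(record, defn, ctx, prior):
    # Free-form trigger: only an explicit reviewer annotation makes it fire.
    if defn.trigger_id in record.manual_triggers:
        return _result(defn, record, Status.positive,
                       [("manual_annotation", defn.trigger_id)])
    return _result(defn, record, Status.negative)


def _eval_sxabcde(record, defn, ctx, prior):
    offending = [
        (step, record.sxabcde_steps[step].value)
        for step in SXABCDE_STEPS
        if record.sxabcde_steps.get(step, SxabcdeStatus.not_assessed)
        is not SxabcdeStatus.assessed_and_addressed
    ]
    if offending:
        return _result(defn, record, Status.positive, offending)
    return _result(defn, record, Status.negative,
                   [("sxabcde", "all steps assessed and addressed")])


def _eval_condition_rules(record, defn, ctx, prior):
    rules = defn.params.get("rules", [])
    view = feature_view(record)
    matched = False
    violations: list[tuple[str, Any]] = []
    for rule in rules:
        applies = evaluate_rule(rule["when"], view)
        if applies is not True:
            continue
        matched = True
        satisfied = evaluate_rule(rule["require"], view)
        if satisfied is not True:
            violations.append(
                (rule.get("id", "condition_rule"),
                 rule_observations(rule["require"], view))
            )
    if not matched:
        return _result(defn, record, Status.not_applicable)
    if violations:
        return _result(defn, record, Status.positive, violations)
    return _result(defn, record, Status.negative,
                   [("condition_rules", "all matched rules satisfied")])


def _eval_absent_vitals(record, defn, ctx, prior):
    required = list(CORE_VITALS)
    if record.chief_complaint in ctx.vocab.glucose_indicated_complaints:
        required.append("blood_glucose")
    missing = [v for v in required if getattr(record.vitals, v) is None]
    if missing:
        return _result(defn, record, Status.positive,
                       [(v, "not measured") for v in missing])
    return _result(defn, record, Status.negative,
                   [("vital_signs", "all indicated vitals measured")])


def _eval_absent_examination(record, defn, ctx, prior):
    exam_map = defn.params.get("exam_map") or ctx.vocab.exam_map
    required = exam_map.get(record.chief_complaint)
    if not required:
        return _result(defn, record, Status.not_applicable)
    missing = [e for e in required if e not in record.examinations]
    if missing:
        return _result(defn, record, Status.positive,
                       [(e, "not performed") for e in missing])
    return _result(defn, record, Status.negative,
                   [("examinations", sorted(record.examinations))])


def _eval_aggregate_any(record, defn, ctx, prior):
    members = defn.params.get("members")
    if not members:
        raise ConfigurationError(
            f"aggregate trigger {defn.trigger_id} needs 'members'"
        )
    positive_members = [
        m for m in members if prior[m].status is Status.positive
    ]
    if positive_members:
        return _result(defn, record, Status.positive,
                       [(m, "positive") for m in positive_members])
    return _result(defn, record, Status.negative,
                   [("members", list(members))])


def _eval_deterioration(record, defn, ctx, prior):
    if record.deterioration_noted:
        return _result(defn, record, Status.positive,
                       [("deterioration_noted", True)])
    panels = record.vitals.repeated_panels
    if len(panels) < 2:
        return _result(defn, record, Status.not_applicable)
    bounds = defn.params.get("red_bounds") or ctx.vocab.retts_red_bounds
    first, last = panels[0].values, panels[-1].values
    crossings: list[tuple[str, Any]] = []
    for vital, (lo, hi) in bounds.items():
        v0, v1 = getattr(first, vital, None), getattr(last, vital, None)
        if v0 is None or v1 is None:
            continue
        if lo <= v0 <= hi and not (lo <= v1 <= hi):
            crossings.append((vital, (v0, v1)))
    if crossings:
        return _result(defn, record, Status.positive, crossings)
    return _result(defn, record, Status.negative,
                   [("repeated_panels", len(panels))])


def _eval_interpreter(record, defn, ctx, prior):
    flags = record.environment_flags
    if not flags.language_barrier_present:
        return _result(defn, record, Status.not_applicable)
    if not flags.interpreter_used:
        return _result(defn, record, Status.positive,
                       [("interpreter_used", False)])
    return _result(defn, record, Status.negative, [("interpreter_used", True)])


_DEFINITIVE = {
    DefinitiveCareType.thrombolysis,
    DefinitiveCareType.pci,
    DefinitiveCareType.intensive_care,
}


def _eval_ed_triage_inconsistency(record, defn, ctx, prior):
    if not record.conveyance.conveyed or record.ed_handover is None:
        return _result(defn, record, Status.not_applicable)
    ho = record.ed_handover
    if ho.direct_to_definitive_care and ho.definitive_care_type in _DEFINITIVE:
        return _result(defn, record, Status.positive,
                       [("definitive_care_type", ho.definitive_care_type.value)])
    return _result(defn, record, Status.negative,
                   [("direct_to_definitive_care", ho.direct_to_definitive_care)])


def _eval_nonconveyance(record, defn, ctx, prior):
    if not record.conveyance.conveyed:
        return _result(defn, record, Status.positive, [("conveyed", False)])
    return _result(defn, record, Status.negative, [("conveyed", True)])


def _eval_return_within_window(record, defn, ctx, prior):
    parent = defn.params.get("parent", "B6")
    if prior[parent].status is not Status.positive:
        return _result(defn, record, Status.not_applicable)
    if record.record_id not in ctx.returns_map:
        raise ConfigurationError(
            f"record {record.record_id} missing from 72-h returns map"
        )
    if ctx.returns_map[record.record_id]:
        return _result(defn, record, Status.positive,
                       [("return_within_72h", True)])
    return _result(defn, record, Status.negative, [("return_within_72h", False)])


def _eval_alternative_transport(record, defn, ctx, prior):
    if not record.conveyance.conveyed:
        return _result(defn, record, Status.not_applicable)
    if record.conveyance.mode in ALTERNATIVE_MODES:
        return _result(defn, record, Status.positive,
                       [("conveyance_mode", record.conveyance.mode.value)])
    return _result(defn, record, Status.negative,
                   [("conveyance_mode", record.conveyance.mode.value)])


def _eval_destination_deviation(record, defn, ctx, prior):
    if not record.conveyance.conveyed:
        return _result(defn, record, Status.not_applicable)
    per_guideline = record.conveyance.destination_per_guideline
    if per_guideline is None:
        return _result(defn, record, Status.not_applicable)
    if per_guideline is False:
        return _result(defn, record, Status.positive,
                       [("destination_per_guideline", False)])
    return _result(defn, record, Status.negative,
                   [("destination_per_guideline", True)])


def _eval_formulary(record, defn, ctx, prior):
    if not record.drugs:
        return _result(defn, record, Status.not_applicable)
    formulary: Mapping[str, Any] = defn.params.get("formulary", {})
    violations: list[tuple[str, Any]] = []
    for admin in record.drugs:
        if admin.guideline_conform is False:
            violations.append((admin.drug_code, "documented as non-conform"))
            continue
        rule = formulary.get(admin.drug_code)
        if rule is None:
            logger.info(
                "drug %s on record %s not in formulary; not evaluable",
                admin.drug_code, record.record_id,
            )
            continue
        max_dose = rule.get("max_dose")
        if max_dose is not None and admin.dose is not None and admin.dose > max_dose:
            violations.append(
                (admin.drug_code, f"dose {admin.dose} above maximum {max_dose}")
            )
        indications = rule.get("indications")
        if indications and admin.indication is not None \
                and admin.indication not in indications:
            violations.append(
                (admin.drug_code, f"indication {admin.indication!r} not listed")
            )
    if violations:
        return _result(defn, record, Status.positive, violations)
    return _result(defn, record, Status.negative,
                   [("drugs", [d.drug_code for d in record.drugs])])


Evaluator = Callable[
    [EMSRecord, TriggerDefinition, ScreeningContext, Mapping[str, TriggerResult]],
    TriggerResult,
]

_EVALUATORS: dict[str, Evaluator] = {
    "documentation": _eval_documentation,
    "response_time": _eval_response_time,
    "on_site_time": _eval_on_site_time,
    "flag_rule": _eval_flag_rule,
    "manual": _eval_manual,
    "sxabcde": _eval_sxabcde,
    "condition_rules": _eval_condition_rules,
    "absent_vitals": _eval_absent_vitals,
    "absent_examination": _eval_absent_examination,
    "aggregate_any": _eval_aggregate_any,
    "deterioration": _eval_deterioration,
    "interpreter": _eval_interpreter,
    "ed_triage_inconsistency": _eval_ed_triage_inconsistency,
    "nonconveyance": _eval_nonconveyance,
    "return_within_window": _eval_return_within_window,
    "alternative_transport": _eval_alternative_transport,
    "destination_deviation": _eval_destination_deviation,
    "formulary": _eval_formulary,
}


def _dependencies(defn: TriggerDefinition) -> tuple[str, ...]:
    if defn.kind == "aggregate_any":
        return tuple(defn.params.get("members", ()))
    if defn.kind == "return_within_window":
        return (defn.params.get("parent", "B6"),)
    return ()


def evaluate_trigger(
    record: EMSRecord,
    defn: TriggerDefinition,
    ctx: ScreeningContext,
    prior: Mapping[str, TriggerResult] | None = None,
) -> TriggerResult:
    """Evaluate one trigger definition on one record.  ``prior`` supplies
    already-computed results for dependency kinds (aggregates, subtriggers)."""
    return _EVALUATORS[defn.kind](record, defn, ctx, dict(prior or {}))


def screen_record(
    record: EMSRecord, registry: TriggerRegistry, ctx: ScreeningContext
) -> ScreeningResult:
    """Run every active trigger against one record.

    Deterministic: a pure function of (record, registry, context).  Exactly
    one result per active trigger, in registry order.
    """
    results: dict[str, TriggerResult] = {}
    ordered: list[TriggerResult] = []
    for defn in registry.active():
        res = evaluate_trigger(record, defn, ctx, results)
        results[defn.trigger_id] = res
        ordered.append(res)
    return ScreeningResult(record_id=record.record_id, results=tuple(ordered))


def screen_cohort(
    records: Sequence[EMSRecord],
    registry: TriggerRegistry,
    vocab: Vocabulary | None = None,
    returns_map: Mapping[str, bool] | None = None,
    linkage_records: Sequence[EMSRecord] | None = None,
) -> list[ScreeningResult]:
    """Screen a cohort of records.

    The 72-h returns map is built automatically (over ``linkage_records``
    when given, so that contacts outside the reviewed sample still count as
    returns) unless supplied explicitly.
    """
    if returns_map is None:
        returns_map = link_returns(linkage_records or records)
    ctx = ScreeningContext(vocab=vocab or Vocabulary.default(),
                           returns_map=returns_map)
    return [screen_record(r, registry, ctx) for r in records]
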