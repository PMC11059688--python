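"""A small declarative predicate grammar over record fields.

Registry entries and condition-specific guideline rules are written as
predicate trees so that regional configurations can adjust trigger
criteria without touching code.  A node is one of::

    {"field": <dotted path>, "op": <comparator>, ["value": <literal>]}
    {"all": [<node>, ...]}
    {"any": [<node>, ...]}
    {"not": <node>}

Comparators: ``eq ne lt le gt ge in contains is_true is_false present
absent``.  Field paths resolve against a *feature view* of the record —
the record's own fields plus derived quantities such as
``response_time_min``, ``on_site_time_min`` and ``drug_codes`` — so every
leaf references either a schema field or a documented derived feature.

Evaluation is three-valued: ``True``, ``False``, or ``None`` when a
referenced value is absent (missing data never makes a rule positive).
"""

from __future__ import annotations

from datetime import datetime
from typing import Any, Mapping, Optional

from .records import EMSRecord

COMPARATORS = (
    "eq", "ne", "lt", "le", "gt", "ge",
    "in", "contains", "is_true", "is_false", "present", "absent",
)


class RuleError(ValueError):
    """Malformed rule specification."""


def minutes_between(t0: Optional[datetime], t1: Optional[datetime]) -> Optional[int]:
    """Duration in whole minutes, rounding down; None when either end is
    missing."""
    if t0 is None or t1 is None:
        return None
    return int((t1 - t0).total_seconds() // 60)


def feature_view(record: EMSRecord) -> dict[str, Any]:
    """Flat view of a record: schema fields plus derived features."""
    view: dict[str, Any] = record.model_dump()
    view["response_time_min"] = minutes_between(
        record.mission_start, record.on_scene_arrival
    )
    view["on_site_time_min"] = minutes_between(
        record.on_scene_arrival, record.scene_departure
    )
    view["drug_codes"] = sorted(d.drug_code for d in record.drugs)
    view["conveyed"] = record.conveyance.conveyed
    view["conveyance_mode"] = record.conveyance.mode.value
    return view


def _resolve(path: str, view: Mapping[str, Any]) -> Any:
    value: Any = view
    for part in path.split("."):
        if isinstance(value, Mapping):
            if part not in value:
                return None
            value = value[part]
        else:
            value = getattr(value, part, None)
        if value is None:
            return None
    return value


def _leaf(node: Mapping[str, Any], view: Mapping[str, Any]) -> Optional[bool]:
    op = node.get("op")
    if op not in COMPARATORS:
        raise RuleError(f"unknown comparator {op!r}")
    observed = _resolve(node["field"], view)
    if op == "present":
        return observed is not None
    if op == "absent":
        return observed is None
    if observed is None:
        return None
    if op == "is_true":
        return bool(observed) is True
    if op == "is_false":
        return bool(observed) is False
    value = node.get("value")
    if op == "eq":
        return observed == value
    if op == "ne":
        return observed != value
    if op == "lt":
        return observed < value
    if op == "le":
        return observed <= value
    if op == "gt":
        return observed > value
    if op == "ge":
        return observed >= value
    if op == "in":
        return observed in value
    if op == "contains":
        return value in observed
    raise RuleError(f"unhandled comparator {op!r}")  # pragma: no cover


def evaluate_rule(node: Mapping[str, Any], view: Mapping[str, Any]) -> Optional[bool]:
    """Evaluate a predicate tree against a feature view (three-valued)."""
    if "all" in node:
        results = [evaluate_rule(child, view) for child in node["all"]]
        if any(r is False for r in results):
            return False
        if any(r is None for r in results):
            return None
        return True
    if "any" in node:
        results = [evaluate_rule(child, view) for child in node["any"]]
        if any(r is True for r in results):
            return True
        if any(r is None for r in results):
            return None
        return False
    if "not" in node:
        inner = evaluate_rule(node["not"], view)
        return None if inner is None else not inner
    if "field" in node:
        return _leaf(node, view)
    raise RuleError(f"malformed rule node: {dict(node)!r}")


def rule_observations(
    node: Mapping[str, Any], view: Mapping[str, Any]
) -> list[tuple[str, Any]]:
    """Collect (field, observed value) pairs for every leaf of a rule —
    used to build trigger evidence."""
    out: list[tuple[str, Any]] = []
    if "field" in node:
        out.append((node["field"], _resolve(node["field"], view)))
    for key in ("all", "any"):
        for child in node.get(key, ()):
            out.extend(rule_observations(child, view))
    if "not" in node:
        out.extend(rule_observations(node["not"], view))
    return out
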