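"""Validation statistics for the trigger tool.

Implements the evaluation surface of a trigger-tool study:

* per-trigger positive predictive values (PPV) split by incident class
  (near miss / no-harm / harmful), as ``class count / positives x 100``;
* the item-level content validity index (I-CVI): the share of expert
  raters scoring a trigger 3 or 4 on a 4-point relevance scale, with the
  conventional 0.80 cut-off for "highly relevant";
* paired-rater agreement on the record x trigger grid: the 2x2 confusion
  matrix, observed agreement, Cohen's kappa, and the prevalence- and
  bias-adjusted kappa PABAK = 2*p_o - 1 (trigger review grids are
  dominated by negatives, which depresses kappa; PABAK corrects for
  that imbalance);
* cohort frequency reports (WHO classes, NCC MERP categories, per-trigger
  positives, demographics).

Degenerate inputs (zero positives for a PPV; expected agreement of 1 for
kappa) yield the explicit ``UNDEFINED`` sentinel rather than a silent zero
or NaN.  Printed tables in the field sometimes truncate rather than round
percentages, so every presentation helper takes a ``mode`` of ``"round"``
(default) or ``"truncate"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import EMSRecord
from .triggers import ScreeningResult, Status
from .workflow import Judgement, IncidentClassification, WhoClass, WHO_SEVERITY


class _Undefined:
    """Sentinel for statistics that are undefined on the given input."""

    _instance: Optional["_Undefined"] = None

    def __new__(cls) -> "_Undefined":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"


UNDEFINED = _Undefined()


def truncate(value: float, decimals: int = 1) -> float:
    """Truncate toward zero at the given number of decimals."""
    factor = 10**decimals
    return math.trunc(value * factor) / factor


def present(value: float, decimals: int = 1, mode: str = "round") -> float:
    if mode == "round":
        return round(value, decimals)
    if mode == "truncate":
        return truncate(value, decimals)
    raise ValueError(f"unknown presentation mode {mode!r}")


# ---------------------------------------------------------------------------
# Paired-rater agreement


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Paired binary assessments: a = both positive, b = rater1 negative /
    rater2 positive, c = rater1 positive / rater2 negative, d = both
    negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one cell")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_confusion_matrix(
    assessments1: Mapping[tuple[str, str], bool],
    assessments2: Mapping[tuple[str, str], bool],
) -> ConfusionMatrix2x2:
    """Tally two raters' binary outcomes over the identical
    (record, trigger) grid; the unit of analysis is one grid cell."""
    if set(assessments1) != set(assessments2):
        raise ValueError("raters must cover the identical (record, trigger) grid")
    a = b = c = d = 0
    for cell, r1 in assessments1.items():
        r2 = assessments2[cell]
        if r1 and r2:
            a += 1
        elif not r1 and r2:
            b += 1
        elif r1 and not r2:
            c += 1
        else:
            d += 1
    return ConfusionMatrix2x2(a, b, c, d)


def grid_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], bool]:
    """Flatten a records x triggers boolean DataFrame into grid cells."""
    return {
        (str(rec), str(trig)): bool(frame.at[rec, trig])
        for rec in frame.index
        for trig in frame.columns
    }


def observed_agreement(cm: ConfusionMatrix2x2) -> float:
    """Proportion of cells on which the raters agree: (a + d) / n."""
    return (cm.a + cm.d) / cm.n


def cohens_kappa(cm: ConfusionMatrix2x2) -> float | _Undefined:
    """Chance-corrected agreement, with chance from the marginal products.

    Returns :data:`UNDEFINED` when the expected agreement is 1 (both raters
    constant), where kappa has no value.
    """
    n = cm.n
    p_o = observed_agreement(cm)
    p_pos = ((cm.a + cm.c) / n) * ((cm.a + cm.b) / n)
    p_neg = ((cm.b + cm.d) / n) * ((cm.c + cm.d) / n)
    p_e = p_pos + p_neg
    if math.isclose(p_e, 1.0):
        return UNDEFINED
    return (p_o - p_e) / (1.0 - p_e)


def pabak(cm: ConfusionMatrix2x2) -> float:
    """Prevalence- and bias-adjusted kappa: 2 * observed agreement - 1."""
    return 2.0 * observed_agreement(cm) - 1.0


_KAPPA_BANDS = (
    (0.21, 0.40, "fair"),
    (0.41, 0.60, "moderate"),
    (0.61, 0.80, "substantial"),
    (0.81, 1.00, "almost_perfect"),
)


def interpret_kappa(value: float) -> str:
    """Interpretation band for a kappa-type coefficient (closed intervals
    0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00
    almost perfect; anything lower is 'below_fair')."""
    if not -1.0 <= value <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    for lo, hi, label in _KAPPA_BANDS:
        # compare at two decimals so e.g. 0.405 does not fall between bands
        if lo <= round(value, 2) <= hi:
            return label
    return "below_fair"


def agreement_report(
    cm: ConfusionMatrix2x2, mode: str = "round"
) -> dict[str, object]:
    """Matrix, observed agreement, kappa, PABAK and their bands in one dict."""
    kappa = cohens_kappa(cm)
    pb = pabak(cm)
    return {
        "matrix": {"a": cm.a, "b": cm.b, "c": cm.c, "d": cm.d, "n": cm.n},
        "observed_agreement": present(observed_agreement(cm), 2, mode),
        "cohens_kappa": kappa if kappa is UNDEFINED else present(kappa, 2, mode),
        "kappa_band": None if kappa is UNDEFINED else interpret_kappa(float(kappa)),
        "pabak": present(pb, 2, mode),
        "pabak_band": interpret_kappa(pb),
    }


# ---------------------------------------------------------------------------
# Trigger performance (PPV)


@dataclass(frozen=True)
class TriggerPerformance:
    trigger_id: str
    positives: int
    near_miss: int
    no_harm: int
    harmful: int
    ppv_near_miss: float | _Undefined
    ppv_no_harm: float | _Undefined
    ppv_harmful: float | _Undefined


def trigger_ppv(
    trigger_id: str,
    positives: int,
    near_miss: int,
    no_harm: int,
    harmful: int,
    mode: str = "round",
) -> TriggerPerformance:
    """PPV per incident class: class count / positives x 100 (one decimal).

    With zero positives the PPVs are :data:`UNDEFINED`, never 0.
    """
    if positives < 0 or min(near_miss, no_harm, harmful) < 0:
        raise ValueError("counts must be non-negative")
    if near_miss + no_harm + harmful > positives:
        raise ValueError("incident-class counts exceed trigger positives")

    def ppv(count: int) -> float | _Undefined:
        if positives == 0:
            return UNDEFINED
        return present(count / positives * 100.0, 1, mode)

    return TriggerPerformance(
        trigger_id=trigger_id,
        positives=positives,
        near_miss=near_miss,
        no_harm=no_harm,
        harmful=harmful,
        ppv_near_miss=ppv(near_miss),
        ppv_no_harm=ppv(no_harm),
        ppv_harmful=ppv(harmful),
    )


_CLASS_FIELD = {
    WhoClass.near_miss: "near_miss",
    WhoClass.no_harm_incident: "no_harm",
    WhoClass.harmful_incident: "harmful",
}


def trigger_performance_table(
    screenings: Sequence[ScreeningResult],
    incidents: Iterable[Judgement],
    mode: str = "round",
) -> pd.DataFrame:
    """Per-trigger positives and incident-class PPVs from a reviewed cohort.

    Each judged incident attributes its WHO class to the triggers it is
    linked to; a trigger positive on a record with several linked incidents
    counts under the most severe class.
    """
    from .workflow import merp_to_who  # local import to avoid cycle at import time

    positives: dict[str, int] = {}
    order: list[str] = []
    positive_cells: dict[str, set[str]] = {}
    for s in screenings:
        for r in s.results:
            if r.trigger_id not in positives:
                positives[r.trigger_id] = 0
                order.append(r.trigger_id)
                positive_cells[r.trigger_id] = set()
            if r.status is Status.positive:
                positives[r.trigger_id] += 1
                positive_cells[r.trigger_id].add(s.record_id)

    # worst incident class attributed per (trigger, record)
    cell_class: dict[tuple[str, str], WhoClass] = {}
    for j in incidents:
        if not j.incident_present or j.category is None:
            continue
        who = merp_to_who(j.category)
        for t in j.linked_triggers:
            key = (t, j.record_id)
            if key not in cell_class or WHO_SEVERITY[who] > WHO_SEVERITY[cell_class[key]]:
                cell_class[key] = who

    rows = []
    for t in order:
        tallies = {"near_miss": 0, "no_harm": 0, "harmful": 0}
        for rec in positive_cells[t]:
            who = cell_class.get((t, rec))
            if who is not None and who in _CLASS_FIELD:
                tallies[_CLASS_FIELD[who]] += 1
        perf = trigger_ppv(
            t, positives[t], tallies["near_miss"], tallies["no_harm"],
            tallies["harmful"], mode,
        )
        rows.append(perf.__dict__)
    return pd.DataFrame(rows).set_index("trigger_id")


# ---------------------------------------------------------------------------
# Content validity


@dataclass(frozen=True)
class LikertRatingSet:
    trigger_id: str
    dimension: str  # clinical_relevance | comprehensibility | utility
    ratings: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.ratings:
            raise ValueError("at least one rater is required")
        if any(r not in (1, 2, 3, 4) for r in self.ratings):
            raise ValueError("ratings must be on the 4-point scale {1,2,3,4}")


@dataclass(frozen=True)
class ICVIResult:
    value: float
    highly_relevant: bool


def icvi(ratings: LikertRatingSet, threshold: float = 0.80) -> ICVIResult:
    """Item-level content validity index: share of raters scoring 3 or 4,
    two decimals, flagged highly relevant at the 0.80 threshold."""
    share = sum(1 for r in ratings.ratings if r >= 3) / len(ratings.ratings)
    value = round(share, 2)
    return ICVIResult(value=value, highly_relevant=value >= threshold)


# ---------------------------------------------------------------------------
# Frequency reporting


@dataclass
class FrequencyReport:
    n: int
    who_summary: pd.DataFrame
    merp_summary: pd.DataFrame
    trigger_summary: pd.DataFrame
    demographics: pd.DataFrame

    def to_dict(self) -> dict[str, object]:
        return {
            "n": self.n,
            "who": self.who_summary.reset_index().to_dict(orient="records"),
            "merp": self.merp_summary.reset_index().to_dict(orient="records"),
            "triggers": self.trigger_summary.reset_index().to_dict(orient="records"),
            "demographics": self.demographics.to_dict(orient="records"),
        }


def _count_frame(
    counts: Mapping[str, int], n: int, mode: str, label: str
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            label: list(counts.keys()),
            "count": list(counts.values()),
        }
    )
    df["percent"] = [present(c / n * 100.0, 1, mode) for c in df["count"]]
    return df.set_index(label)


def frequency_report(
    classifications: Sequence[IncidentClassification],
    screenings: Sequence[ScreeningResult],
    cohort: Sequence[EMSRecord],
    mode: str = "round",
    return_subtrigger: str = "B6_RETURN_72H",
    return_parent: str = "B6",
) -> FrequencyReport:
    """Cohort summary tables: WHO classes, NCC MERP categories, per-trigger
    positives (the 72-h-return subtrigger is expressed as a share of
    non-conveyed positives, as in the field's reporting convention), and
    demographics.
    """
    n = len(cohort)
    class_by_record = {c.record_id: c for c in classifications}
    missing = {s.record_id for s in screenings} - set(class_by_record)
    if missing:
        raise ValueError(
            f"classification missing for records: {sorted(missing)[:5]}"
        )

    who_counts = {w.value: 0 for w in WhoClass}
    for c in classifications:
        who_counts[c.who_class.value] += 1
    who_summary = _count_frame(who_counts, n, mode, "who_class")

    merp_counts: dict[str, int] = {}
    for c in classifications:
        key = c.final_category.value if c.final_category else "none"
        merp_counts[key] = merp_counts.get(key, 0) + 1
    merp_summary = _count_frame(merp_counts, n, mode, "merp_category")

    trig_counts: dict[str, int] = {}
    order: list[str] = []
    for s in screenings:
        for r in s.results:
            if r.trigger_id not in trig_counts:
                trig_counts[r.trigger_id] = 0
                order.append(r.trigger_id)
            if r.status is Status.positive:
                trig_counts[r.trigger_id] += 1
    rows = []
    for t in order:
        base = n
        if t == return_subtrigger and trig_counts.get(return_parent):
            base = trig_counts[return_parent]
        pct = (
            present(trig_counts[t] / base * 100.0, 1, mode) if base else UNDEFINED
        )
        rows.append({"trigger_id": t, "positives": trig_counts[t], "percent": pct})
    trigger_summary = pd.DataFrame(rows).set_index("trigger_id")

    demo_rows = []
    def tally(variable: str, values: Iterable[str]) -> None:
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        for value, count in sorted(counts.items()):
            demo_rows.append(
                {
                    "variable": variable,
                    "value": value,
                    "count": count,
                    "percent": present(count / n * 100.0, 1, mode),
                }
            )

    tally("sex", (r.patient_sex.value for r in cohort))
    tally("dispatch_priority", (str(r.dispatch_priority) for r in cohort))
    tally("triage_colour", (r.triage_colour.value for r in cohort))
    tally("conveyance_mode", (r.conveyance.mode.value for r in cohort))
    demographics = pd.DataFrame(demo_rows)

    return FrequencyReport(
        n=n,
        who_summary=who_summary,
        merp_summary=merp_summary,
        trigger_summary=trigger_summary,
        demographics=demographics,
    )
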