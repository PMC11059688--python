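# Methods

## The screening model

A trigger is a predicate over one structured ambulance mission record. The
engine is deliberately three-valued: `positive` (criteria met), `negative`
(criteria evaluable and not met) and `not_applicable` (the record is
outside the trigger's scope, or the data needed to evaluate it are
absent). Absence of data never produces a positive — incomplete
documentation is itself a trigger (A1), so letting missing timestamps or
vitals fire *other* triggers would double-count the documentation failure.
Every positive result carries evidence: the criteria that failed and the
observed values, so a reviewer can audit any hit.

Screening is a pure function of (record, registry, context): repeated runs
are bit-identical, and each active trigger yields exactly one result per
record.

### Trigger registry

The registry is YAML; each entry has an id, title, group (A general care
environment, B care process, L medication), a `kind` naming the evaluator,
and parameters. Simple flag triggers (weather, equipment failure, resource
shortage, transport harm, drug mix-up, drug shortage) and the
condition-specific guideline rules use a small declarative predicate
grammar (`field/op/value` leaves under `all`/`any`/`not` combinators,
documented in `emstrigger.rules`) so that regional configurations need no
code changes. Two profiles ship:

* `rrr900` — all 23 entries active (the full set used during a 900-record
  review: A1–A7, B1 with subtriggers B1A–B1D, B2–B8 plus the B6 72-h
  return subtrigger, L1–L3);
* `final` — the revised set with A7 ("Other") retired; A7 never fired in
  review and rated lowest on utility. Retiring A7 leaves 18 top-level
  triggers (19 when the 72-h return subtrigger is counted separately).
  Which trigger was actually dropped in the revision is not public; this
  choice is the package's own reconstruction.

Decisions embedded in the rules, where the published material leaves the
operational detail open:

* **Strict inequalities at time boundaries.** "Response time > 20 min" and
  "time on site > 10 min" are strict: exactly 20 (10) minutes is negative.
  Durations are computed in whole minutes, rounding down, on
  timezone-naive local timestamps.
* **"Life-threatening condition"** for the on-scene-time trigger (A3)
  defaults to RETTS-A red triage; the predicate is configurable.
* **A1's five documentation criteria** are a configurable reconstruction:
  chief complaint, complete core vital-sign panel, triage outcome,
  interventions/drugs with dose, and conveyance-decision rationale, each
  documented or not. A1 is positive when at least one is unmet, and is
  monotone: marking one more criterion missing can never clear it.
* **B1 (guideline deviation)** is the disjunction of its subtriggers:
  SX-ABCDE step not assessed or not addressed (B1A); configurable
  condition-specific rules (B1B; defaults: chest pain without aspirin,
  hypoglycaemic loss of consciousness without glucose — illustrative,
  meant to be replaced by regional guidelines); any of the five core
  vitals absent, plus blood glucose when the complaint is loss of
  consciousness or seizure (B1C); required examination for the chief
  complaint absent (B1D, from a complaint → examination map; complaints
  without an entry are not applicable).
* **Deterioration (B3)** compares the first and last repeated vitals panel
  during transport: positive when a vital that started inside its RETTS-A
  red bound ends outside it, or when an explicit deterioration note is
  set; fewer than two panels is not applicable.
* **72-h return (B6 subtrigger).** The window is half-open from the index
  mission's start: a contact at exactly t0 does not count, one at exactly
  t0 + 72 h does. Linkage uses a pseudonymous patient key; records without
  one are excluded from linkage and logged.
* **Judgement-dependent triggers** (B1B, B3, B8, L1) are operationalized
  as declarative rules with explicit not-evaluable outcomes (e.g. a drug
  absent from the formulary is logged, not positive), because in practice
  they are applied by humans reading free text. A7 fires only on an
  explicit manual annotation.

## The review workflow

Reviewer judgement is always an explicit input artifact (a CSV judgement
table or the synthetic reviewer) — the engine never infers clinical
judgement. Two workflow versions are implemented: `original` (primary
grades AB/C/D; C and D route to secondary review) and `revised` (primary
grades only AB/C; any incident with risk of harm routes ungraded to the
secondary reviewer, who uses AB/C/D without harm and E–I with harm, plus
harm type and preventability 1–4). A record with several incidents takes
the most severe incident's class (ordering: no incident < near miss <
no-harm < harmful); incident counts are preserved separately. Validation
is strict: judgements may only reference triggers that screened positive,
secondary grades must be consistent with the harmed flag, and a required
secondary review cannot be absent.

## Sampling

Records are bucketed by calendar year-month of mission start and
`min(k, bucket)` are drawn per bucket without replacement (default
k = 25). The stream is an explicitly seeded MT19937; the draw is a partial
Fisher–Yates shuffle over the bucket sorted by (mission start, record id),
so the selection is reproducible across platforms and independent of input
order. Undersized buckets are included in full with a warning, mirroring
review practice.

## Statistics

* **PPV** per trigger and incident class: class count / positives × 100,
  one decimal. Zero positives yield an explicit `UNDEFINED` sentinel, not
  zero.
* **I-CVI**: share of expert raters scoring 3 or 4 on the 4-point
  relevance scale, two decimals, flagged highly relevant at ≥ 0.80. The
  computation is rater-count-agnostic.
* **Agreement** on the record × trigger grid: observed agreement
  p_o = (a+d)/n; Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the
  marginal products (`UNDEFINED` when p_e = 1); PABAK = 2·p_o − 1.
  Interpretation bands (closed intervals): 0.21–0.40 fair, 0.41–0.60
  moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect; below 0.21 is
  reported as `below_fair`. Trigger grids are negative-dominated, so κ is
  systematically deflated relative to PABAK; the property κ ≤ PABAK under
  prevalence imbalance with small bias is covered by tests.
* **Presentation.** Published tables in this field are inconsistent
  between rounding and truncation (e.g. a PABAK of 0.8959 printed as 0.89
  but an accuracy of 0.94798 printed as 0.95). All statistics are computed
  at full precision; presentation helpers offer `round` (default) and
  `truncate` modes, and reports that mirror printed tables use whichever
  convention the table used. Output always uses a decimal point.
* In the frequency report the 72-h-return subtrigger is expressed as a
  share of non-conveyed (B6) positives, not of the whole cohort, following
  the reporting convention for that subtrigger.

Cohen's κ, PABAK, PPV and I-CVI are implemented here (they are the tool's
validation surface); the test suite cross-checks κ against scikit-learn's
`cohen_kappa_score` as an independent oracle.

## Synthetic cohorts

`CohortSpec` defaults describe the study conditions of a national
ambulance record review: 900 records over 12 months, 9 of them violating
the adult/primary-mission inclusion criteria (leaving 891), demographics
(sex ≈ 52 % female; priorities ≈ 41/54/5 %; RETTS-A colour mix with ≈ 9 %
red and ≈ 7 % missing; complaint mix led by dyspnoea, chest pain and
abdominal pain; age ≈ N(67, 18) clipped to ≥ 18), per-trigger prevalences
(e.g. non-conveyance 20.8 %, absent examination 16.2 %, incomplete
documentation 14.4 %), a per-trigger incident model P(class | trigger
positive), and a 15.1 % 72-h return rate among the non-conveyed.

Planting is independent per trigger except structural couplings:
response-time positives are planted only on priority-1 dispatches,
on-scene-time positives only on red triage, the B1D/B1B conditions only on
complaints where they are defined, and the conveyance triggers are
mutually constrained (a non-conveyed record cannot also have an
alternative transport mode, destination deviation or ED handover).
Conditioned triggers are planted within their eligible stratum at rate
p/P(stratum), keeping the unconditional prevalence equal to the specified
one; a spec whose prevalence exceeds its stratum share is rejected as
infeasible. Planted 72-h returns materialize as an extra linked contact
record (`mission_type=other`) outside the reviewed sample, the way a
real return would appear in the source system. Every generated record is
otherwise "perfect": with all prevalences at zero the whole cohort screens
clean, so any screened positive is attributable to a planted condition,
and screening recovers the manifest exactly.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data:

* **Trigger co-occurrence.** Real guideline deviations cluster within
  records; under independent planting the derived B1 aggregate rate is
  ≈ 0.33 rather than the ≈ 0.30 a clustered cohort shows, and record-level
  incident shares run a few points above the per-trigger model (several
  independent incidents can land on one record). Manifest-based checks are
  exact regardless; rate-based checks use binomial bands around the
  *planted* rates.
* **Free-text clinical narrative.** Judgement-dependent triggers are
  planted through structured fields; nothing here validates human
  interpretation of prose records.
* **Case-mix realism** beyond the marginal distributions above (no
  seasonality, no within-patient correlation except planted returns).

The synthetic reviewers close the loop: `simulate_judgements` derives a
deterministic judgement table from the manifest (near misses → AB without
risk of harm; no-harm incidents → C, or D via the risk-of-harm route for a
configurable share; harmful incidents → E/G with harm type and
preventability), so classification reproduces the planted WHO classes
exactly in both workflow versions. `simulate_raters` perturbs the truth
grid per cell with per-rater sensitivity/specificity for agreement
experiments.

## Problem sizes and numerical conventions

The test suite and acceptance script use cohorts of 900 records for
end-to-end recovery (the review's own scale), 10,000 records for
prevalence-convergence checks (3σ binomial bands), 10,000 seeds × 10
records for sampling uniformity (chi-square), and exhaustive enumeration
for small discrete spaces (all 4⁶ six-rater Likert vectors; a 2⁷ record
space for the rule-engine oracle). All randomness flows from explicit
seeds; generation, screening, sampling and the CLI pipeline are
byte-reproducible for a fixed seed.

## Known limitations

* The record schema is a reconstruction from published summary tables and
  trigger definitions; real journal systems differ per region, which is
  why the vocabulary, documentation criteria, examination map, condition
  rules and formulary are all configuration, shipped with defaults.
* The exact composition of the revised (`final`) trigger profile and the
  published A1 documentation criteria are not public; both defaults are
  marked reconstructions.
* No confidence intervals for κ/PABAK and no multi-rater (Fleiss-type)
  generalization; the agreement module covers exactly two raters.
* Non-conveyance (B6) is a *screening* trigger here; whether non-conveyance
  was clinically appropriate is a reviewer judgement, not a rule.
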