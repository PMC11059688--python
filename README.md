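# emstrigger

A computable **ambulance trigger tool** for patient-safety review in
prehospital emergency care (EMS).

Spontaneous incident reporting misses most adverse events in ambulance
care, where a patient typically meets only one crew. A *trigger tool*
complements it: during a structured retrospective record review, each
completed mission record is screened against predefined triggers — clues
such as "response time > 20 min on a lights-and-sirens dispatch", "a core
vital sign was never measured", or "non-conveyed patient returned within
72 h". Positive records then pass a two-stage review: a nurse decides
whether the triggers point at an incident and grades it on the NCC MERP
severity index (A–I, with A and B fused as *AB*); incidents with a risk of
harm go to a physician who grades harm (E–I), harm type and preventability
(1–4). MERP categories map onto WHO incident classes:

    none → no incident    AB → near miss (NM)
    C, D → no-harm incident (NHI)    E–I → harmful incident (HI)

`emstrigger` implements that whole pipeline over structured EMS mission
records, plus the validation statistics used to evaluate such a tool:

* **rule engine** — 23 triggers in groups A (general), B (care process,
  including the B1 guideline-deviation subtriggers B1A–B1D and the B6
  72-hour-return subtrigger) and L (medication), configurable via YAML
  registries (`rrr900` and `final` profiles ship with the package) and a
  small declarative predicate grammar; missing data yield
  `not_applicable`, never a positive;
* **record model & I/O** — validated mission records (timeline, RETTS-A
  triage, vitals, SX-ABCDE steps, drugs, conveyance, documentation flags)
  with lossless CSV/JSON round-trips and 72-h return linkage on a
  pseudonymous patient key;
* **sampling** — month-stratified selection (default 25/month) with a
  seeded Mersenne Twister and partial Fisher–Yates draw;
* **statistics** — per-trigger PPV by incident class, item-level content
  validity index (I-CVI), paired-rater confusion matrices with observed
  agreement, Cohen's κ = (p_o − p_e)/(1 − p_e), PABAK = 2·p_o − 1, and the
  standard interpretation bands;
* **synthetic cohorts** — a generator that plants trigger conditions and
  incidents at configurable prevalence and emits a ground-truth manifest,
  plus simulated reviewers, so the full pipeline is testable without
  confidential patient data.

## Worked example

```python
from emstrigger import (ConfusionMatrix2x2, cohens_kappa, observed_agreement,
                        pabak, interpret_kappa, truncate)

# two nurses screened the same 90 records against 22 triggers
cm = ConfusionMatrix2x2(a=59, b=69, c=34, d=1818)   # a=both positive ... d=both negative
print(round(observed_agreement(cm), 2))   # 0.95
print(round(cohens_kappa(cm), 1))         # 0.5   -> interpret_kappa: "moderate"
print(truncate(pabak(cm), 2))             # 0.89  -> "almost_perfect"
```

Observed agreement is 0.95, but κ is only 0.5: trigger grids are dominated
by negative cells, which deflates κ (the prevalence problem). PABAK
adjusts for prevalence and bias and lands at 0.89 — almost perfect.

The full pipeline on a synthetic cohort:

```python
from emstrigger import (apply_inclusion_criteria, classify_cohort,
                        frequency_report, load_registry, screen_cohort)
from emstrigger.synthetic import CohortSpec, generate_cohort, simulate_judgements

records, manifest = generate_cohort(CohortSpec(n_records=900, n_ineligible=9, seed=2024))
eligible = [r for r in records if apply_inclusion_criteria(r)]   # 891 records
screenings = screen_cohort(eligible, load_registry("rrr900"), linkage_records=records)
cohort = classify_cohort(screenings, simulate_judgements(manifest))
print(frequency_report(cohort.classifications, screenings, eligible).who_summary)
```

prints the WHO class table for the 891 reviewed records, e.g.

```
                  count  percent
no_incident         404     45.3
near_miss           425     47.7
no_harm_incident     58      6.5
harmful_incident      4      0.4
```

and `cohort.who_counts() == manifest.who_counts()` holds exactly: the
screened triggers and final classes equal the planted ground truth.
More narrative scripts live in `examples/` (screening a single record,
monthly sampling, PPV and I-CVI), and a thin CLI wraps the library:

```bash
emstrigger pipeline --n 900 --ineligible 9 --seed 7 --out-dir run/
```

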