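"""Month-stratified record selection with a reproducible seed.

A year of eligible missions is bucketed by calendar month and 25 records
are drawn per month with a seeded Mersenne Twister — the scheme that yields
300 reviewed records per organization per year.  Rerunning with the same
seed reproduces the selection exactly; a different seed gives a different
(equally valid) sample.
"""

from emstrigger import SamplingPlan, sample_monthly, stratify_by_month
from emstrigger.synthetic import CohortSpec, generate_cohort

records, _ = generate_cohort(CohortSpec(n_records=1200, n_ineligible=0, seed=3))
buckets = stratify_by_month(records)
print("monthly bucket sizes:",
      {f"{y}-{m:02d}": len(b) for (y, m), b in buckets.items()})

plan = SamplingPlan(per_month_count=25, seed=42)
selection = sample_monthly(buckets, plan)
again = sample_monthly(buckets, plan)
other = sample_monthly(buckets, SamplingPlan(per_month_count=25, seed=43))

print(f"selected {len(selection)} records (25 per month)")
print("same seed reproduces the draw:", selection == again)
print("different seed differs:", selection != other)
print("first five ids:", selection[:5])
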