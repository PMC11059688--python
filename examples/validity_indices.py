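"""Trigger validity: positive predictive value and content validity index.

PPV answers "when this trigger fires, how often does it point at a real
incident of each class?" — class count over total positives, x100.  The
I-CVI answers "do the expert reviewers consider this trigger relevant?" —
the share of raters scoring it 3 or 4 on a 4-point scale, with >= 0.80
conventionally read as highly relevant.
"""

from emstrigger import LikertRatingSet, icvi, trigger_ppv

# per-trigger review tallies: (positives, near misses, no-harm, harmful)
tallies = {
    "B1 deviation from treatment guidelines": (271, 238, 24, 1),
    "A3 time on site >10 min, life-threatening": (19, 16, 0, 0),
    "B6 non-conveyance after assessment": (185, 102, 5, 1),
    "L1 inappropriate drug treatment": (2, 0, 2, 0),
    "A4 weather affected care": (0, 0, 0, 0),
}
print("trigger PPVs (% of positives per incident class):")
for name, (pos, nm, nh, hi) in tallies.items():
    perf = trigger_ppv(name, pos, nm, nh, hi)
    print(f"  {name}: positives={pos}  near-miss={perf.ppv_near_miss}"
          f"  no-harm={perf.ppv_no_harm}  harmful={perf.ppv_harmful}")
print("(UNDEFINED means the trigger never fired: no PPV exists, "
      "which is not the same as 0.)\n")

panel = {
    "clinical_relevance": (3, 4, 2, 3, 4, 3),
    "comprehensibility": (4, 4, 4, 4, 4, 4),
    "utility": (4, 3, 4, 3, 4, 2),
}
print("I-CVI for one trigger across six expert raters:")
for dimension, ratings in panel.items():
    result = icvi(LikertRatingSet("A2", dimension, ratings))
    flag = "highly relevant" if result.highly_relevant else "below threshold"
    print(f"  {dimension}: {result.value:.2f} ({flag})")
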