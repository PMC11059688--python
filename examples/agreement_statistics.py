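"""Paired-rater agreement on a trigger review grid.

Two nurses independently screened the same 90 records against 22 triggers;
each (record, trigger) cell is positive or negative.  From the resulting
2x2 confusion matrix we compute observed agreement, Cohen's kappa and
PABAK.  Kappa is depressed because almost all cells are negative (a
prevalence problem); PABAK corrects for that, which is why the two
coefficients land in different interpretation bands.
"""

from emstrigger import (
    ConfusionMatrix2x2,
    agreement_report,
    cohens_kappa,
    interpret_kappa,
    observed_agreement,
    pabak,
    truncate,
)

sessions = {
    "session one": ConfusionMatrix2x2(a=59, b=69, c=34, d=1818),
    "session two": ConfusionMatrix2x2(a=31, b=53, c=60, d=1836),
}

for name, cm in sessions.items():
    kappa = cohens_kappa(cm)
    print(f"{name}: n = {cm.n} cells (90 records x 22 triggers)")
    print(f"  observed agreement = {observed_agreement(cm):.2f}")
    print(f"  Cohen's kappa      = {kappa:.2f}  ({interpret_kappa(kappa)})")
    print(f"  PABAK              = {truncate(pabak(cm), 2):.2f}  "
          f"({interpret_kappa(pabak(cm))})")

print()
print("bundled report:", agreement_report(sessions["session one"]))
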