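"""Ploidy-adjusted copy-number events and shared alterations.

PACN thresholds: < 1e-6 homozygous deletion, <= 0.5 deletion, >= 1.5 gain,
>= 2.5 amplification. A shared alteration is the least severe category
present in every sequenced metastasis of a patient; genes altered in only
a subset are reported as divergent.
"""

from methet.genomics import pacn_to_event
from methet.io import analyze_cohort
from methet.synthetic import SyntheticCohortConfig, generate_cohort

for pacn in (0.0, 0.3, 0.5, 1.0, 1.5, 2.5, 4.2):
    print(f"PACN {pacn:>4} -> {pacn_to_event(pacn)}")

samples, genomic, clinical, truth = generate_cohort(SyntheticCohortConfig(), seed=11)
res = analyze_cohort(samples, genomic_input=genomic, n_boot=200, seed=11)

events = res["genomic_events"]
print("\nshared event counts across the cohort:")
print(events.groupby(["gene", "event"]).size().to_string())

flags = res["genomic_flags"]
n_ar = sum(f["AR_altered"] for f in flags.values())
n_rb_tp = sum(f["RB1&TP53_altered"] for f in flags.values())
print(f"\nAR-altered patients: {n_ar}/{len(flags)}")
print(f"combined RB1+TP53 loss: {n_rb_tp}/{len(flags)}")
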