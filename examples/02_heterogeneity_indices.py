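"""Heterogeneity indices and their bootstrap summaries.

The heterogeneity index (HI) is the probability, scaled to 0-100, that two
samples drawn without replacement from one patient carry discordant labels
(subtype, or Ki-67 dichotomized at 20%). Cohort means get BCa bootstrap
95% confidence intervals.
"""

from methet.heterogeneity import (
    bootstrap_mean_ci,
    ki67_patient_hi,
    subtype_hi,
)
from methet.io import analyze_cohort
from methet.synthetic import SyntheticCohortConfig, generate_cohort

# small worked examples first
hi = subtype_hi({"AR+/NE-": 3, "AR+/NE+": 1})
print(f"counts 3+1 -> HI = {hi.value:.1f} "
      f"({hi.n_discordant}/{hi.n_pairs} discordant pairs)")
print(f"Ki-67 [10, 20, 21, 80] -> HI = "
      f"{ki67_patient_hi([10, 20, 21, 80]).value:.1f} (20 counts as low)")

# full cohort
samples, genomic, clinical, _ = generate_cohort(SyntheticCohortConfig(), seed=3)
res = analyze_cohort(samples, n_boot=1000, seed=3)
ps = res["patient_summary"]

print(f"\nheterogeneous patients: {ps['heterogeneous'].sum()}/{len(ps)}")
b = res["hi_bootstrap"]
print(f"mean subtype HI {b.point_estimate:.1f} "
      f"(95% BCa CI {b.ci_low:.1f}-{b.ci_high:.1f})")
kb = res["ki67_hi_bootstrap"]
print(f"mean Ki-67 HI  {kb.point_estimate:.1f} "
      f"(95% BCa CI {kb.ci_low:.1f}-{kb.ci_high:.1f})")

# bootstrap of an arbitrary statistic's inputs works on plain lists too
vals = ps.loc[ps.hi_defined, "hi"].tolist()
print(f"\nsame CI recomputed directly: "
      f"{bootstrap_mean_ci(vals, n_boot=1000, seed=4).ci_low:.1f}-"
      f"{bootstrap_mean_ci(vals, n_boot=1000, seed=4).ci_high:.1f}")
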