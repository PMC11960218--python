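"""Compositional multilevel model: does reporting bias differ by sex?

Each child's device and self-report compositions become ILR coordinates
stacked in long format; a mixed model with nested random intercepts (wave,
school, child) and per-ILR random effects tests the method × characteristic
interaction and back-transforms model estimates to min/day per level.
"""

import dataclasses

from timeuse import coda, matching, synthetic as syn

# plant a sex-specific reporting difference: boys under-report MVPA,
# girls over-report it (each by 30 min/day, traded against LPA)
boys = dataclasses.replace(syn.zero_bias(), mvpa_shift_min=-30.0)
girls = dataclasses.replace(syn.zero_bias(), mvpa_shift_min=+30.0)
cfg = syn.CohortConfig(
    n_participants=150, days_per_participant=4, seed=14,
    bias=syn.zero_bias(), bias_by_sex={"male": boys, "female": girls},
    nonwear_mean_min=0, nonwear_sd_min=0, schedule_grid_min=5,
    person_dispersion=0.04, day_dispersion=0.03, academic_missing_prob=0.0)
table = matching.records_from_study(syn.generate_study(cfg))

res = coda.run_characteristic_analysis(table, "sex")
print(f"omnibus method x sex interaction: chi2 = {res.chi2:.1f}, "
      f"df = {res.df}, p = {res.p:.2g}  (n = {res.n})")
print(f"random structure: {res.random_structure}\n")

print("model-based compositions (min/day, rows sum to 1440):")
print(res.estimates.round(0).to_string(index=False))

print("\npattern per behaviour (device -> self, male vs female):")
for b, label in res.patterns.items():
    print(f"  {b:<6} {label}")
print("\nMVPA is 'inverting': the sex gap reverses between methods —"
      "\nboys do more measured MVPA, girls report more.")
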