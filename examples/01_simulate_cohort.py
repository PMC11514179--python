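"""Simulate an ever-smoker cohort with a known lung-cancer hazard model.

The simulator emulates a large prospective smoking cohort: realistic
marginals (age 57.4 (7.9), BMI 27.8 (4.8), cigarettes/day heaped to
multiples of five), a deterministic pack-years identity, and a rare
right-censored time-to-event outcome driven by a known Cox model.
"""
import numpy as np

import synthcohort as sc

schema = sc.default_schema()
true_model = sc.default_true_model()

cov = sc.simulate_covariates(schema, n=20_000, seed=0)
cohort = sc.simulate_outcomes(cov, true_model, seed=1)

d = cohort.data
print(f"n = {cohort.n}")
print(f"age mean (sd)            {d['age'].mean():6.2f} ({d['age'].std():.2f})")
print(f"cigarettes/day mean (sd) {d['cigarettes_per_day'].mean():6.2f} "
      f"({d['cigarettes_per_day'].std():.2f})")
mult5 = np.mean(d["cigarettes_per_day"] % 5 == 0)
print(f"fraction reporting a multiple of 5 cigarettes: {mult5:.2f} (heaping)")
print(f"events observed: {int(cohort.event.sum())} "
      f"({100 * cohort.event.mean():.1f}% over ~13y of follow-up)")
p5 = np.mean((cohort.event == 1) & (cohort.time <= 5))
print(f"5-year event prevalence: {100 * p5:.2f}% (rare-event regime)")
print("informative features:", sorted(sc.true_feature_set(true_model, schema)))

cohort.to_csv("scratch_cohort.csv")  # + JSON schema side-car
print("wrote scratch_cohort.csv (CSV + .schema.json side-car)")
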