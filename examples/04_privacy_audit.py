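"""Audit a synthetic dataset: k-anonymity and membership inference.

k-anonymity measures reidentification risk over quasi-identifiers; the
density-ratio membership-inference AUC measures whether training members can
be told apart from non-members using only the synthetic data.
"""
import synthcohort as sc
from synthcohort.generators import GanConfig, sample, train_gan
from synthcohort.preprocess import Encoder
from synthcohort.privacy import domias, k_anonymity

schema = sc.default_schema()
train = sc.simulate_covariates(schema, 2000, 0)
nonmembers = sc.simulate_covariates(schema, 1000, 1)
reference = sc.simulate_covariates(schema, 1000, 2)

enc = Encoder.from_cohort(train)
model, ledger = train_gan(enc.transform(train),
                          GanConfig(method="adsgan", epochs=100, seed=3,
                                    epsilon_budget=float("inf")))
synth = sample(model, 2000, seed=4, encoder=enc)
print("generator note:", ledger.note)

k = k_anonymity(synth.cohort)   # age (5-year bins), sex, ethnicity
print(f"k-anonymity of the synthetic table: {k} "
      "(every quasi-identifier combination is shared by >= k records)")

rep = domias(synth.values, enc.transform(train).values[:1000],
             enc.transform(nonmembers).values, enc.transform(reference).values)
print(f"membership-inference AUC: {rep.mia_auc:.3f} "
      "(0.5 = attacker can do no better than chance)")
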