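"""Run the whole study end to end and write a report bundle.

Equivalent to `synthstudy run --config study.yaml`; at this desk scale it
takes a few minutes on one CPU.
"""
from synthcohort.study import StudyConfig, report_markdown, run_study

config = StudyConfig(
    n_cohort=3000, seed=0, methods=("adsgan", "dpgan"), n_members=2,
    gan_overrides={"all": {"epochs": 30}}, bic_ks=(2, 10),
    output_dir="scratch_study",
)
report = run_study(config)
print(report_markdown(report))
print("\nartifacts written to scratch_study/ "
      "(synthetic CSVs, privacy ledgers, report.json, manifest)")
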