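"""Generate a synthetic ward cohort with planted sepsis episodes.

Builds 300 admissions at the default 6.25% sepsis prevalence and prints the
cohort summary: the planted prevalence is exact by construction, lengths of
stay are log-normal within the 24 h - 50 day inclusion band, and every
admission carries irregular labs, EWS-triggered vitals and clinical events.
"""

import json

import clinframe as cf

synth = cf.generate_cohort(cf.GeneratorConfig(n_admissions=300, seed=42))
print(json.dumps(cf.describe_cohort(synth), indent=2))

# The three interchange tables (plus SOFA ground truth) can be written out
# for the CLI or any external tool:
#   cf.write_cohort(synth.cohort, "cohort_dir")
#   synth.sofa.to_csv("cohort_dir/sofa.csv", index=False)
print(f"\nplanted positives: {int(synth.ground_truth['planted'].sum())} "
      f"of {synth.cohort.n_admissions} admissions")
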