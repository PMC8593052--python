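"""Featurize observation windows and compare vital-sign missingness.

Each sample's 12-h observation window becomes 50 features: hourly means are
pooled into two 6-h timesteps, one-sided gaps are filled by forward/backward
imputation, and the late values plus the timestep differences (delta) form
the vector.  Because vitals are recorded when EWS assessments happen, the
on-clinical-demand framing — whose prediction times *are* those assessments —
sees far fewer missing vitals than a clock-driven sliding window.
"""

import clinframe as cf

synth = cf.generate_cohort(cf.GeneratorConfig(n_admissions=300, seed=42))
provider = cf.sofa_provider_from_table(synth.cohort, synth.sofa)
labels = cf.label_cohort(synth.cohort, cf.Sepsis3Config(), provider)

features = {}
for structure in ("sliding_window", "on_clinical_demand"):
    cfg = cf.FramingConfig(structure=structure, seed=0)
    samples = cf.frame_cohort(synth.cohort, labels, cfg, sofa_provider=provider)
    features[structure] = cf.featurize_samples(synth.cohort, samples)
    print(f"{structure}: {len(samples)} samples x "
          f"{features[structure].shape[1] - 2} features")

report = cf.missingness_report(features)
vitals = synth.cohort.schema.vitals
print("\npercent missing per vital sign:")
print(report.loc[vitals].round(2).to_string())
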