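"""The four framing structures applied to one cohort.

The same labeled admissions produce radically different supervised datasets
depending on when predictions are asked for: once per admission (fixed time
to onset), every 6 h (sliding window), every 6 h after the first organ
dysfunction (dynamic inclusion), or at each staff EWS assessment (on
clinical demand).  The induced class ratio 1:N widens along exactly that
order, which is the property that drives AUPRC, Brier and ACE differences
between otherwise identical models.
"""

import clinframe as cf

synth = cf.generate_cohort(cf.GeneratorConfig(n_admissions=300, seed=42))
provider = cf.sofa_provider_from_table(synth.cohort, synth.sofa)
labels = cf.label_cohort(synth.cohort, cf.Sepsis3Config(), provider)

print(f"{'structure':<26}{'samples':>9}{'pos':>6}{'neg':>8}  ratio")
for structure in (
    "fixed_time_to_onset",
    "on_clinical_demand",
    "sliding_window_dynamic",
    "sliding_window",
):
    cfg = cf.FramingConfig(structure=structure, seed=0)
    samples = cf.frame_cohort(synth.cohort, labels, cfg, sofa_provider=provider)
    bal = cf.class_balance(samples)
    print(
        f"{structure:<26}{len(samples):>9}{bal.positives:>6}{bal.negatives:>8}  {bal.ratio_text}"
    )
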