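# clinframe

Temporal **framing** of machine-learning risk prediction on longitudinal
clinical records, illustrated end to end on sepsis onset prediction in
general hospital wards.

Before any model is trained, a clinical prediction problem must be *framed*:
what exactly is predicted, at which **prediction times**, from which
retrospective **observation window**, and over which prospective
**prediction window** must the outcome fall for a label to be positive.
These choices — not the learner — largely determine the class balance of the
resulting supervised dataset and therefore the apparent performance of any
model trained on it.  `clinframe` makes the framing an explicit, testable
object.

The package is aimed at data scientists and clinical-informatics researchers
who build or review inpatient deterioration models and want to quantify how
framing choices move discrimination and calibration metrics.

## What it implements

* **Cohort I/O** (`clinframe.cohort`) — a three-table long format
  (admissions, measurements, events) in plain CSV, with strict validation,
  referential integrity, and the 24 h–50 day length-of-stay inclusion
  filter.  The measurement schema is closed: 19 laboratory tests plus 6
  vital signs (25 parameters).
* **Sepsis-3 labeling** (`clinframe.sepsis`, `clinframe.sofa`) — suspected
  infection from culture/antibiotic event pairs (culture→antibiotic ≤ 72 h,
  antibiotic→culture ≤ 24 h; index = the earlier event), and onset at the
  earliest hour *t* in the window `[index − 48 h, index + 24 h]` where the
  SOFA score satisfies `SOFA(t) − min{SOFA(u): u ≤ t, u in window} ≥ 2`.
  SOFA series are pluggable: precomputed scores, or scored from raw
  measurements with a configurable per-organ component table.
* **Four framing structures** (`clinframe.framing`) —
  `fixed_time_to_onset` (one right-aligned sample per admission),
  `sliding_window` (prediction grid every `shift` hours),
  `sliding_window_dynamic` (the same grid, gated on the first SOFA > 0), and
  `on_clinical_demand` (one sample per staff EWS assessment).  Labels are
  half-open interval memberships `onset ∈ (t + lead, t + lead + W_pred]`,
  with post-onset censoring.
* **Feature pipeline** (`clinframe.features`) — 12-h observation windows →
  hourly means → two 6-h timesteps → forward/backward imputation → 25 late
  values + 25 timestep differences (Δ) = 50 features, plus per-structure
  missingness reporting.  Nothing after the prediction time can enter a
  feature.
* **Evaluation bench** (`clinframe.metrics`, `clinframe.bench`) —
  patient-grouped fivefold cross-validation (80/10/10
  train/validation/test), five model families (extra trees, random forest,
  LightGBM, XGBoost, logistic regression), AUROC/AUPRC, the **stratified
  Brier score** (per-class mean squared error × 100) and the **average
  calibration error** (ACE: unweighted mean over equal-width probability
  bins of |observed event fraction − mean predicted probability|, in %).
* **Synthetic ward EHR** (`clinframe.simulate`) — seeded cohorts with
  planted sepsis episodes (qualifying event pairs, ≥ 2-point SOFA rises,
  vital-sign ramps), EWS-triggered vitals, ~daily lab panels with heavy
  missingness, and exact ground truth for every planted onset.

## Worked example

```python
import clinframe as cf

synth = cf.generate_cohort(cf.GeneratorConfig(n_admissions=300, seed=42))
provider = cf.sofa_provider_from_table(synth.cohort, synth.sofa)
labels = cf.label_cohort(synth.cohort, cf.Sepsis3Config(), provider)

for structure in ("fixed_time_to_onset", "on_clinical_demand",
                  "sliding_window_dynamic", "sliding_window"):
    cfg = cf.FramingConfig(structure=structure, seed=0)
    samples = cf.frame_cohort(synth.cohort, labels, cfg, sofa_provider=provider)
    bal = cf.class_balance(samples)
    print(structure, len(samples), bal.ratio_text)
```

prints

```
fixed_time_to_onset 300 1:15
on_clinical_demand 1785 1:24
sliding_window_dynamic 2760 1:72
sliding_window 3714 1:97
```

Same cohort, same labeler, same 6.3% admission-level prevalence — yet the
supervised datasets range from 300 samples at 1:15 to 3714 samples at 1:97,
purely because of *when* predictions are asked for.  The labeler itself
recovers 100% of the generator's planted onsets within 6 h on this cohort
(median grid error 0.42 h).  The `examples/` directory walks through each
capability (simulation, labeling, framing, featurization/missingness,
benchmarking) as short narrative scripts; a thin `clinframe` CLI exposes the
same steps as subcommands (`simulate`, `validate`, `filter`, `label`,
`frame`, `featurize`, `benchmark`).

## Layout

```
src/clinframe/     library modules (cohort, sofa, sepsis, framing,
                   features, metrics, bench, simulate, cli)
examples/          one narrative script per capability
tests/             pytest suite incl. brute-force oracle cross-checks
scripts/           acceptance.py (end-to-end reproduction)
docs/methods.md    model, assumptions, parameter choices, limitations
```
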