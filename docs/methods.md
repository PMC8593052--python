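# Methods

This note documents the models and procedures `clinframe` implements, the
parameter defaults and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical conventions that make
the pipeline deterministic and leakage-free.

## Time model and window conventions

All times are continuous hours relative to an arbitrary per-cohort epoch
(plain floats, no datetimes or time zones).  Every window in the package is
a half-open interval `(a, b]`, so an observation falling exactly on a
boundary belongs to exactly one window:

* a measurement at exactly the prediction time belongs to the observation
  window; one at exactly `t − W_obs` does not;
* an onset at exactly `t + lead + W_pred` labels the sample positive.

The length-of-stay inclusion filter keeps admissions with
`24 h ≤ LOS ≤ 50 days`, reading both bounds strictly ("shorter than" /
"longer than"), so stays of exactly 24 h or exactly 50 days are retained.
Measurements and events timestamped outside their admission interval are
rejected at validation rather than silently used: pre-admission laboratory
results are a different data-provenance regime and admitting them would make
the leakage guarantees unverifiable.

## Sepsis-3 labeling

**Suspected infection (SI).** Within one admission, every
(culture, antibiotic) event pair is evaluated independently: culture-first
pairs qualify if the antibiotic follows within 72 h, antibiotic-first pairs
if the culture follows within 24 h.  The SI index time is the earlier member
of the pair.  Overlapping pairs are all kept; since only the earliest
resulting onset is reported, deduplication would change nothing.  Multiple
antibiotic administrations are treated as independent events rather than
collapsed into courses.

**Organ dysfunction.** For each SI event the window
`[index − 48 h, index + 24 h]`, clipped to the admission and discretized on
an hourly grid, is scanned for the earliest time `t` with
`SOFA(t) − min{SOFA(u): u in window, u ≤ t} ≥ 2`.  The running-minimum
baseline operationalizes "acute increase": a patient who enters the window
already at SOFA 5 and stays there is not acutely deteriorating, whereas a
rise from any within-window trough of two or more points is.  The
admission's onset is the earliest qualifying `t` over all SI events.  We
deliberately define onset as the *SOFA-increase time*, not the SI index
time; this is the single most consequential labeling convention in the
package, and the ground-truth comparisons in the tests pin it down
explicitly.

**SOFA provenance.** The labeler accepts any per-admission SOFA series.
Either precomputed scores are forward-filled onto the hourly grid (grid
points before the first recorded score default to 0), or raw measurements
are scored with a component table.  The default table covers the four organ
systems computable from the packaged 25-parameter ward schema — coagulation
(platelets), liver (bilirubin), renal (creatinine) and cardiovascular (mean
arterial pressure from cuff blood pressures) — with the consensus
thresholds.  Respiration (requires FiO2) and CNS (requires GCS) are not
observable in this schema; any component whose inputs were never measured
contributes 0 points (*missing-as-normal*).  This floor-biases the total on
sparsely measured admissions, which is conservative for onset detection:
missing data can never manufacture a two-point rise.

## Framing structures

All four structures share the labeling rule
`label = 1 ⇔ onset ∈ (t + lead, t + lead + W_pred]` and post-onset
censoring: samples of a positive admission at or after onset are dropped,
because "will this patient develop sepsis?" is ill-posed once they have.
Defaults are `W_obs = 12 h`, `W_pred = 12 h`, `lead = 0`, `shift = 6 h`.

* **Fixed time to onset** — positives get exactly one sample at
  `onset − 12 h` (dropped when that precedes admission); negatives one
  sample at a uniform random time in the admission, drawn from a seeded
  generator so the dataset is reproducible.  This is the naive
  case-control framing: strongest apparent metrics, weakest clinical
  meaning, since it conditions on future information.
* **Sliding window** — prediction times `admit + W_obs + k · shift` up to
  and including discharge.  Starting at `admit + W_obs` means the first
  sample already has a full observation window; starting earlier would
  systematically truncate early windows.
* **Sliding window with dynamic inclusion** — the *same* grid, restricted
  to times at or after the first grid hour with SOFA > 0.  We intentionally
  do not re-anchor the grid at the inclusion time: keeping the grid fixed
  makes the dynamic sample set a strict subset of the sliding one, and —
  because a Sepsis-3 onset implies a SOFA rise beginning no later than
  onset — the positive samples of the two structures coincide.  That subset
  property is the structure's entire point (discard samples known to be
  negative without losing positives) and is asserted in the tests.
* **On clinical demand** — one sample per EWS assessment event, at that
  event's time; the sampling rate is whatever the physicians chose.  No
  grid arithmetic is involved.

Prediction windows that extend past discharge for negative admissions still
yield label 0; right-censoring is ignored, as sliding-window designs
conventionally do.

## Feature pipeline

Per sample: measurements in `(t − 12, t]` are averaged within 1-h bins
anchored at `t` (sample-relative, not clock-aligned — anchoring at the
prediction time makes features invariant to the admission's absolute clock
phase); hourly values are pooled into an early `(−12, −6]` and a late
`(−6, 0]` timestep; a missing late value is filled from the early one and
vice versa (forward/backward imputation, idempotent); the feature vector is
the 25 late-timestep values plus 25 differences `Δ = late − early`.  The
late timestep supplies the base values because recency carries the most
clinical signal.  When one timestep was imputed from the other, Δ is exactly
0; when both are missing, both the value and Δ stay missing (NaN).

Residual missingness is preserved.  Models that consume NaN natively
(LightGBM, XGBoost) receive it as-is; for the others a median imputer is
fitted *on the training split only* inside the model adapter (plus
train-fitted standardization for the logistic regression).  There is no
global imputation or scaling step, so no statistic of the test fold ever
reaches training.

A vectorized batch featurizer produces the same numbers as the composed
per-step reference path (asserted element-exactly in the tests), and a
poisoning test verifies that corrupting every measurement after the
prediction time changes no feature.

## Evaluation

**Cross-validation.** Patients (not admissions, not samples) are shuffled
once per seed and split into five 20% portions; fold *i* trains on the other
four and halves portion *i* into validation and test.  All samples of a
patient inherit the patient's role, so repeat admissions cannot straddle
train and test.  Validation is used only for early stopping of the boosting
families.

**Metrics.**  AUROC (midrank tie convention) and AUPRC (step-integrated
precision–recall) via scikit-learn; both require both classes in the test
fold, and a fold without positives marks the cell undefined rather than
aborting the run.  The stratified Brier score is
`mean((1 − p)²) × 100` over positives and `mean(p²) × 100` over negatives,
reported separately so that calibration quality in the rare class is not
drowned by the majority.  ACE uses 10 equal-width, right-closed bins over
[0, 1] (probability 0 goes to the first bin); empty bins are excluded and
the per-bin absolute gaps |event rate − mean predicted probability| are
averaged *unweighted*, which is what makes the metric informative under
imbalance.  "Fraction of correct predictions" per bin is read as the
observed event rate, the standard interpretation for binary risk scores.
Per-fold metrics are summarized as mean ± t(0.975, k−1)·sd/√k.

Hyperparameters are library defaults with a fixed seed throughout; the
benchmark is about framings, not model tuning.

## Synthetic cohort generator

The generator targets the *pipeline's assumptions*, not any real cohort's
epidemiology.  What it emulates, with defaults and rationale:

| condition | default | why |
|---|---|---|
| sepsis prevalence | 6.25% of admissions, planted deterministically (round-half-up of n·prevalence) | typical general-ward prevalence; deterministic planting makes fixture prevalences exact and tests stable |
| length of stay | log-normal, median ≈ 72 h, clipped to 24 h–50 d | ward stays are right-skewed; the band matches the inclusion filter so generated cohorts pass it unchanged |
| EWS assessments | every ~16 h (jitter ±4 h), extra assessments during deterioration | physician-driven schedules are irregular and intensify when patients worsen |
| vitals | recorded at EWS times, ~2% dropout (5% for temperature) | on wards, vitals exist because someone assessed the patient — this is what makes the on-clinical-demand framing see almost-complete vitals while 12-h sliding windows miss ~25–30% |
| labs | ~daily panels, each parameter present with p = 0.7 | produces the heavy (~60–70%) per-window lab missingness typical of ward data |
| sepsis episode | SOFA 0→1 at onset − 24 h, 1→2 at onset; culture at onset − 2 h, antibiotic at onset + 1 h; linear vital ramp over 24 h; correlated lab deterioration | satisfies the Sepsis-3 pairing and ≥2-point-rise conditions by construction, giving exact ground truth; the early SOFA 1 also guarantees the dynamic-inclusion subset property for positives |
| severity | per-patient ramp multiplier ~ U(0.3, 1.0) | septic physiology is heterogeneous; without it every positive is trivially separable and models saturate near-perfect scores, which no real ward model achieves |
| negatives | stationary noise around per-patient baselines; 80% get a benign SOFA of 1 (never 2) from a random early time; 15% get a lone decoy antibiotic or culture | ward patients are sick: benign one-point organ scores keep dynamic inclusion from discarding most negatives, and decoys exercise the pairing logic's rejection branches without ever forming a qualifying pair |

Everything is drawn from one `numpy` generator seeded by the config, so
identical seeds give byte-identical cohort files.

What the generator does **not** emulate: comorbidity and demographic
structure, treatment feedback (antibiotics do not bend trajectories),
non-sepsis deterioration competing with the planted episodes, inter-parameter
physiological correlation beyond the shared ramp, or registry artifacts
(unit changes, duplicate charting conventions).  Consequently, passing
benchmarks here demonstrate that the pipeline is correct and that the
qualitative framing-vs-metric relationships hold under controlled conditions
— not that any absolute metric level would transfer to real data.

## Problem sizes

The test suite exercises the labeler/framing oracles on hundreds to a
thousand randomized admissions, ground-truth recovery on a 200-admission
cohort, and the framing-ordering benchmark on 2000 admissions with one
model family — sizes chosen so the full suite completes in a few minutes
while keeping every stochastic assertion comfortably away from its
threshold.  `scripts/acceptance.py` uses the same 2000-admission
configuration.

## Known limitations

* The SOFA component table is a ward-realistic subset (4 of 6 organ
  systems); with precomputed SOFA series this does not affect labeling.
* Sequential learners (RNN/transformer families) and the framing structures
  that would suit them (whole-admission sequences, at-event, random time to
  onset) are out of scope; the framing configuration object is the natural
  extension point.
* ACE's bin count (10) and empty-bin exclusion are conventions; comparisons
  across studies using other binning schemes are not exact.
* Negative "onset" times in fixed-time-to-onset framing are drawn over the
  whole admission, with the observation window clipped at admission start;
  alternatives (e.g., excluding the first hours) would change the missing
  data profile of negatives.
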