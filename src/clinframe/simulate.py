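"""Synthetic general-ward EHR cohorts with planted Sepsis-3 episodes.

The generator emulates the statistical structure the pipeline assumes rather
than any real cohort's epidemiology: admissions of 24 h to 50 days with
log-normal length of stay; irregular, heavily missing labs (~daily panels);
vital signs recorded when staff perform EWS assessments (~every 16 h, more
often as a patient deteriorates); and, for a deterministically planted
fraction of admissions, a sepsis episode consisting of

* a culture/antibiotic pair satisfying the Sepsis-3 pairing windows around
  the planted onset,
* a ground-truth SOFA series rising 0 -> 1 at ramp start and 1 -> 2 at onset
  (a >= 2-point acute increase inside the suspected-infection window),
* consistent laboratory deterioration (platelets and creatinine crossing
  SOFA component thresholds) and a linear pre-onset vital-sign ramp (rising
  pulse, respiratory frequency and temperature; falling blood pressure and
  SpO2).

Negative admissions receive stationary noise, optional decoy events (a lone
antibiotic or culture that can never form a qualifying pair) and, for most,
a benign SOFA of 1 from some early time, so dynamic-inclusion framing keeps
a realistic majority of negative samples.  Everything is reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigurationError
from .schema import DEFAULT_SCHEMA, ParameterSchema

# per-parameter (baseline mean, between-patient sd, within-patient noise sd,
# septic drift added linearly over the ramp, lower clip, upper clip)
_LAB_MODEL: dict[str, tuple[float, float, float, float, float, float]] = {
    "P(aB)-Hydrogen carbonate": (24.0, 2.5, 1.5, -5.0, 5.0, 45.0),
    "P(aB)-Potassium": (4.0, 0.35, 0.2, 0.4, 2.0, 7.5),
    "P-Bilirubin": (11.0, 6.0, 3.0, 16.0, 1.0, 400.0),
    "P(aB)-pO2": (11.0, 1.4, 1.0, -2.2, 4.0, 20.0),
    "B-Leukocytes": (8.5, 3.0, 1.5, 7.0, 0.5, 40.0),
    "P-Potassium": (4.0, 0.35, 0.2, 0.4, 2.0, 7.5),
    "P(aB)-pCO2": (5.3, 0.6, 0.4, -0.7, 2.0, 12.0),
    "B-Neutrophils": (5.5, 2.5, 1.2, 6.0, 0.2, 35.0),
    "P-Glucose": (6.5, 1.5, 1.0, 2.0, 2.5, 25.0),
    "P(aB)-pH": (7.40, 0.03, 0.02, -0.10, 6.9, 7.7),
    "B-Platelets": (260.0, 70.0, 20.0, -150.0, 5.0, 800.0),
    # ward in-patients commonly carry elevated inflammation markers without
    # sepsis, so negative baselines are broad
    "P-C-reactive protein": (45.0, 40.0, 12.0, 120.0, 0.3, 500.0),
    "P(aB)-Lactate": (1.4, 0.5, 0.35, 2.2, 0.2, 15.0),
    "P-Sodium": (139.0, 3.0, 1.5, -3.0, 120.0, 160.0),
    "eGFR": (80.0, 15.0, 6.0, -30.0, 5.0, 140.0),
    "P(aB)-Sodium": (139.0, 3.0, 1.5, -3.0, 120.0, 160.0),
    "P-Albumin": (36.0, 4.0, 2.0, -7.0, 10.0, 55.0),
    "P(aB)-Chloride": (102.0, 3.0, 1.5, 3.0, 85.0, 125.0),
    "P-Creatinine": (85.0, 25.0, 8.0, 100.0, 30.0, 900.0),
}

_VITAL_MODEL: dict[str, tuple[float, float, float, float, float, float]] = {
    "Systolic blood pressure": (122.0, 12.0, 8.0, -22.0, 60.0, 220.0),
    "Diastolic blood pressure": (72.0, 9.0, 6.0, -11.0, 30.0, 130.0),
    "Respiratory frequency": (16.0, 2.5, 2.0, 7.0, 8.0, 45.0),
    "Pulse": (78.0, 10.0, 6.0, 24.0, 35.0, 190.0),
    "SpO2": (96.5, 1.5, 1.0, -5.0, 70.0, 100.0),
    "Temperature": (36.8, 0.35, 0.3, 1.4, 34.0, 42.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_admissions: int
    prevalence: float = 0.0625
    los_range: tuple[float, float] = (24.0, 1200.0)
    los_log_mean: float = np.log(72.0)
    los_log_sd: float = 0.65
    ews_interval_mean: float = 16.0
    ews_interval_jitter: float = 4.0
    vitals_missingness: float = 0.02
    temperature_missingness: float = 0.05
    lab_interval_mean: float = 24.0
    lab_panel_prob: float = 0.7
    ramp_hours: float = 24.0
    severity_range: tuple[float, float] = (0.3, 1.0)
    si_culture_offset: float = -2.0
    si_abx_offset: float = 1.0
    decoy_rate: float = 0.15
    neg_sofa1_prob: float = 0.8
    neg_sofa1_start_frac: float = 0.3
    repeat_patient_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ConfigurationError("prevalence must lie in [0, 1]")
        if self.n_admissions <= 0:
            raise ConfigurationError("n_admissions must be positive")
        lo, hi = self.los_range
        if lo < 24.0 or hi > 1200.0 or lo >= hi:
            raise ConfigurationError("los_range must lie within [24 h, 50 d] with lo < hi")
        if self.ramp_hours > lo:
            raise ConfigurationError(
                f"pre-onset ramp ({self.ramp_hours} h) exceeds the minimum length of stay ({lo} h)"
            )
        if self.prevalence > 0 and hi < 48.0:
            raise ConfigurationError("planting sepsis requires admissions of at least 48 h")


@dataclass
class SyntheticCohort:
    cohort: Cohort
    ground_truth: pd.DataFrame  # admission_id, planted, planted_onset_time
    sofa: pd.DataFrame  # admission_id, time, score (changepoints)


def planted_positive_count(n_admissions: int, prevalence: float) -> int:
    """Deterministic planting count: round-half-up of n * prevalence."""
    return int(np.floor(n_admissions * prevalence + 0.5))


def _drift_fraction(t: np.ndarray, onset: float, ramp: float) -> np.ndarray:
    """0 before the ramp, linear 0..1 across it, sustained 1 after onset."""
    return np.clip((t - (onset - ramp)) / ramp, 0.0, 1.0)


def generate_cohort(
    cfg: GeneratorConfig, schema: ParameterSchema = DEFAULT_SCHEMA
) -> SyntheticCohort:
    """Draw a complete synthetic cohort; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_admissions

    # admissions -----------------------------------------------------------
    lo, hi = cfg.los_range
    los = np.clip(rng.lognormal(cfg.los_log_mean, cfg.los_log_sd, size=n), lo, hi)
    admit = np.round(rng.uniform(0.0, 24.0 * 365.0, size=n), 1)
    # guard against admit + los - admit rounding just below the inclusion bound
    los = np.where((admit + los) - admit < lo, lo + 1e-6, los)
    los = np.where((admit + los) - admit > hi, hi - 1e-6, los)
    adm_ids = np.array([f"A{i:05d}" for i in range(n)])

    patient_ids = []
    pool: list[str] = []
    next_pid = 0
    for i in range(n):
        if pool and rng.random() < cfg.repeat_patient_prob:
            patient_ids.append(pool[int(rng.integers(len(pool)))])
        else:
            patient_ids.append(f"P{next_pid:05d}")
            pool.append(patient_ids[-1])
            next_pid += 1

    admissions = pd.DataFrame(
        {
            "admission_id": adm_ids,
            "patient_id": patient_ids,
            "admit_time": admit,
            "discharge_time": admit + los,
        }
    )

    # planting -------------------------------------------------------------
    n_pos = planted_positive_count(n, cfg.prevalence)
    eligible = np.nonzero(los >= 48.0)[0]
    if n_pos > len(eligible):
        raise ConfigurationError(
            f"cannot plant {n_pos} positives: only {len(eligible)} admissions are >= 48 h"
        )
    pos_idx = set(rng.choice(eligible, size=n_pos, replace=False).tolist()) if n_pos else set()

    onset_times = np.full(n, np.nan)
    for i in pos_idx:
        # onset at least 24 h into the stay and 6 h before discharge so the
        # SI pair and the detection window fit inside the admission
        onset_times[i] = admit[i] + rng.uniform(24.0, los[i] - 6.0)

    meas_rows: list[tuple] = []
    event_rows: list[tuple] = []
    sofa_rows: list[tuple] = []

    for i in range(n):
        a, d = admit[i], admit[i] + los[i]
        positive = i in pos_idx
        onset = onset_times[i]
        # physiological response magnitude varies between septic patients
        severity = float(rng.uniform(*cfg.severity_range)) if positive else 0.0

        # EWS assessment times ------------------------------------------------
        ews = []
        t = a + max(0.5, rng.normal(2.0, 1.0))
        while t < d:
            ews.append(t)
            t += max(2.0, rng.normal(cfg.ews_interval_mean, cfg.ews_interval_jitter))
        if positive:
            # physicians assess more often as the patient deteriorates
            extra = onset - np.array([22.0, 16.0, 10.0, 5.0, 1.0])
            ews.extend(extra[(extra > a) & (extra < d)].tolist())
        ews = np.unique(np.round(np.asarray(ews, dtype=float), 2))
        ews = ews[(ews >= a) & (ews <= d)]
        for t_e in ews:
            event_rows.append((adm_ids[i], float(t_e), "ews_assessment"))

        # vitals at EWS times -------------------------------------------------
        frac = severity * _drift_fraction(ews, onset, cfg.ramp_hours) if positive else np.zeros(len(ews))
        for vital, (mu, bsd, nsd, drift, vlo, vhi) in _VITAL_MODEL.items():
            base = rng.normal(mu, bsd)
            vals = base + rng.normal(0.0, nsd, size=len(ews)) + drift * frac
            miss_p = cfg.temperature_missingness if vital == "Temperature" else cfg.vitals_missingness
            keep = rng.random(len(ews)) >= miss_p
            for t_m, v in zip(ews[keep], np.clip(vals[keep], vlo, vhi)):
                meas_rows.append((adm_ids[i], float(t_m), vital, float(v)))

        # laboratory panels ---------------------------------------------------
        draws = []
        t = a + rng.uniform(0.5, 12.0)
        while t < d:
            draws.append(t)
            t += max(6.0, rng.normal(cfg.lab_interval_mean, cfg.lab_interval_mean / 4.0))
        draws = np.asarray(draws, dtype=float)
        lfrac = severity * _drift_fraction(draws, onset, cfg.ramp_hours) if positive else np.zeros(len(draws))
        for lab, (mu, bsd, nsd, drift, vlo, vhi) in _LAB_MODEL.items():
            base = rng.normal(mu, bsd)
            present = rng.random(len(draws)) < cfg.lab_panel_prob
            vals = base + rng.normal(0.0, nsd, size=len(draws)) + drift * lfrac
            for t_m, v in zip(draws[present], np.clip(vals[present], vlo, vhi)):
                meas_rows.append((adm_ids[i], float(t_m), lab, float(v)))

        # clinical events -----------------------------------------------------
        if positive:
            culture = float(np.clip(onset + cfg.si_culture_offset, a, d))
            abx = float(np.clip(onset + cfg.si_abx_offset, a, d))
            event_rows.append((adm_ids[i], culture, "culture_sample"))
            event_rows.append((adm_ids[i], abx, "antibiotic_administration"))
        elif rng.random() < cfg.decoy_rate:
            kind = "antibiotic_administration" if rng.random() < 0.5 else "culture_sample"
            event_rows.append((adm_ids[i], float(rng.uniform(a + 1.0, d - 1.0)), kind))

        # ground-truth SOFA changepoints --------------------------------------
        if positive:
            ramp_start = max(a, onset - cfg.ramp_hours)
            sofa_rows.append((adm_ids[i], float(a), 0))
            if ramp_start > a:
                sofa_rows.append((adm_ids[i], float(ramp_start), 1))
            sofa_rows.append((adm_ids[i], float(onset), 2))
        else:
            sofa_rows.append((adm_ids[i], float(a), 0))
            if rng.random() < cfg.neg_sofa1_prob:
                start = a + rng.uniform(0.0, cfg.neg_sofa1_start_frac * los[i])
                if start > a:
                    sofa_rows.append((adm_ids[i], float(start), 1))

    measurements = pd.DataFrame(meas_rows, columns=["admission_id", "time", "parameter", "value"])
    events = pd.DataFrame(event_rows, columns=["admission_id", "time", "kind"])
    cohort = Cohort(admissions, measurements, events, schema)

    ground_truth = pd.DataFrame(
        {
            "admission_id": adm_ids,
            "planted": [int(i in pos_idx) for i in range(n)],
            "planted_onset_time": onset_times,
        }
    )
    sofa = pd.DataFrame(sofa_rows, columns=["admission_id", "time", "score"])
    return SyntheticCohort(cohort, ground_truth, sofa)


def describe_cohort(synthetic: SyntheticCohort) -> dict:
    """Summary statistics of a generated cohort (for fixture documentation)."""
    cohort, truth = synthetic.cohort, synthetic.ground_truth
    n = cohort.n_admissions
    if n == 0:
        return {
            "n_admissions": 0,
            "n_patients": 0,
            "prevalence": 0.0,
            "los_hours": {},
            "measurements_per_admission": 0.0,
            "events_by_kind": {},
        }
    los = (
        cohort.admissions["discharge_time"] - cohort.admissions["admit_time"]
    ).to_numpy(dtype=float)
    return {
        "n_admissions": int(n),
        "n_patients": int(cohort.admissions["patient_id"].nunique()),
        "prevalence": float(truth["planted"].mean()),
        "los_hours": {
            "min": float(los.min()),
            "median": float(np.median(los)),
            "mean": float(los.mean()),
            "max": float(los.max()),
        },
        "measurements_per_admission": float(len(cohort.measurements) / n),
        "events_by_kind": cohort.events["kind"].value_counts().to_dict(),
    }
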