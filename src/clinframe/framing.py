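"""The four temporal framing structures.

A framing structure converts a labeled admission into supervised prediction
samples (admission, prediction time, binary label):

* ``fixed_time_to_onset`` — one sample per admission: at onset minus a fixed
  offset for positives, at a uniform random in-admission time for negatives;
* ``sliding_window`` — prediction times on a regular grid from admission
  start (first time = admit + observation window) to discharge;
* ``sliding_window_dynamic`` — the sliding grid restricted to times at or
  after the first hour with SOFA > 0 (dynamic inclusion);
* ``on_clinical_demand`` — one sample per EWS assessment performed by staff.

Labels are interval memberships strictly after the prediction time: label 1
iff onset lies in ``(t + lead, t + lead + prediction_window]``.  For positive
admissions, samples at or after onset are censored (dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import Admission, Cohort
from .errors import ConfigurationError
from .sepsis import CohortLabels, SepsisOutcome
from .sofa import SofaSeries

STRUCTURES = (
    "fixed_time_to_onset",
    "sliding_window",
    "sliding_window_dynamic",
    "on_clinical_demand",
)

_EPS = 1e-9


@dataclass(frozen=True)
class FramingConfig:
    structure: str = "sliding_window"
    observation_window: float = 12.0
    prediction_window: float = 12.0
    lead_window: float = 0.0
    window_shift: float = 6.0
    onset_offset: float = 12.0  # fixed_time_to_onset only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ConfigurationError(f"unknown framing structure {self.structure!r}")
        for name in ("observation_window", "prediction_window", "lead_window"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.structure.startswith("sliding") and self.window_shift <= 0:
            raise ConfigurationError("window_shift must be > 0 for sliding structures")
        if self.onset_offset <= 0:
            raise ConfigurationError("onset_offset must be > 0")


@dataclass(frozen=True)
class PredictionSample:
    admission_id: str
    prediction_time: float
    label: int
    structure: str
    sample_id: str


@dataclass(frozen=True)
class ClassBalance:
    positives: int
    negatives: int

    @property
    def ratio(self) -> float | None:
        return None if self.positives == 0 else self.negatives / self.positives

    @property
    def ratio_text(self) -> str | None:
        return None if self.positives == 0 else f"1:{round(self.negatives / self.positives)}"


def _label_for(onset: float | None, t: float, cfg: FramingConfig) -> int:
    if onset is None:
        return 0
    lo = t + cfg.lead_window
    hi = lo + cfg.prediction_window
    return int(lo < onset <= hi)


def _mk(admission: Admission, t: float, label: int, cfg: FramingConfig, k: int) -> PredictionSample:
    sid = f"{admission.admission_id}|{cfg.structure}|{k}"
    return PredictionSample(admission.admission_id, float(t), label, cfg.structure, sid)


def frame_fixed_time_to_onset(
    admission: Admission,
    outcome: SepsisOutcome,
    cfg: FramingConfig,
    rng: np.random.Generator,
) -> list[PredictionSample]:
    """One sample per admission, right-aligned on the (real or surrogate) onset.

    Positive admissions are sampled at ``onset - onset_offset`` (dropped when
    that precedes the admission); negatives at a uniform random time during
    the admission.  The rng is always consumed for negatives, never for
    positives, so negative sample times are reproducible per seed.
    """
    if outcome.onset_time is not None:
        t = outcome.onset_time - cfg.onset_offset
        if t <= admission.admit_time or t > admission.discharge_time:
            return []
        return [_mk(admission, t, 1, cfg, 0)]
    t = float(rng.uniform(admission.admit_time, admission.discharge_time))
    return [_mk(admission, t, 0, cfg, 0)]


def _sliding_times(admission: Admission, cfg: FramingConfig) -> np.ndarray:
    start = admission.admit_time + cfg.observation_window
    span = admission.discharge_time - start
    if span < -_EPS:
        return np.empty(0)
    n = int(np.floor(span / cfg.window_shift + _EPS)) + 1
    return start + cfg.window_shift * np.arange(n, dtype=float)


def frame_sliding_window(
    admission: Admission, outcome: SepsisOutcome, cfg: FramingConfig
) -> list[PredictionSample]:
    """Regular prediction grid: admit + obs + k*shift, k = 0, 1, ... <= discharge."""
    onset = outcome.onset_time
    out = []
    for k, t in enumerate(_sliding_times(admission, cfg)):
        if onset is not None and t >= onset - _EPS:
            break  # post-onset censoring
        out.append(_mk(admission, t, _label_for(onset, t, cfg), cfg, k))
    return out


def frame_sliding_dynamic(
    admission: Admission,
    outcome: SepsisOutcome,
    sofa: SofaSeries,
    cfg: FramingConfig,
) -> list[PredictionSample]:
    """Sliding grid restricted to prediction times at/after the first SOFA > 0.

    The grid itself is unchanged (no re-anchoring), so the output is always a
    subset of the plain sliding-window output; when organ dysfunction is
    already present before the earliest positive sample time — as Sepsis-3
    onsets guarantee a SOFA rise no later than onset — the positive samples
    are exactly those of the plain sliding window.
    """
    inclusion = sofa.first_time_above(0)
    if inclusion is None:
        return []
    base_cfg = cfg
    onset = outcome.onset_time
    out = []
    for k, t in enumerate(_sliding_times(admission, base_cfg)):
        if onset is not None and t >= onset - _EPS:
            break
        if t < inclusion - _EPS:
            continue
        out.append(_mk(admission, t, _label_for(onset, t, base_cfg), base_cfg, k))
    return out


def frame_on_clinical_demand(
    admission: Admission,
    outcome: SepsisOutcome,
    events: pd.DataFrame,
    cfg: FramingConfig,
) -> list[PredictionSample]:
    """One sample per EWS assessment; the sample interval is whatever the
    physicians chose.  Labeling and post-onset censoring as for sliding."""
    onset = outcome.onset_time
    if len(events) == 0:
        return []
    times = np.sort(events.loc[events["kind"] == "ews_assessment", "time"].to_numpy(dtype=float))
    out = []
    for k, t in enumerate(times):
        if onset is not None and t >= onset - _EPS:
            break
        out.append(_mk(admission, float(t), _label_for(onset, float(t), cfg), cfg, k))
    return out


def class_balance(samples: pd.DataFrame | Iterable[PredictionSample]) -> ClassBalance:
    if isinstance(samples, pd.DataFrame):
        labels = samples["label"].to_numpy(dtype=int) if len(samples) else np.empty(0, dtype=int)
    else:
        labels = np.array([s.label for s in samples], dtype=int)
    pos = int((labels == 1).sum())
    return ClassBalance(pos, int(len(labels) - pos))


SAMPLE_COLUMNS = ["sample_id", "admission_id", "prediction_time", "label", "structure"]


def frame_cohort(
    cohort: Cohort,
    labels: CohortLabels,
    cfg: FramingConfig,
    sofa_provider=None,
) -> pd.DataFrame:
    """Apply one framing structure to every admission of a cohort.

    Returns a samples table (sample_id, admission_id, prediction_time, label,
    structure).  ``sofa_provider`` is required for the dynamic-inclusion
    structure.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    event_groups = {k: g for k, g in cohort.events.groupby("admission_id")}
    empty_events = cohort.events.iloc[0:0]
    rows: list[PredictionSample] = []
    for adm in cohort.iter_admissions():
        outcome = labels.outcome(adm.admission_id)
        if cfg.structure == "fixed_time_to_onset":
            rows.extend(frame_fixed_time_to_onset(adm, outcome, cfg, rng))
        elif cfg.structure == "sliding_window":
            rows.extend(frame_sliding_window(adm, outcome, cfg))
        elif cfg.structure == "sliding_window_dynamic":
            if sofa_provider is None:
                raise ConfigurationError("sliding_window_dynamic requires a sofa_provider")
            sofa = sofa_provider(adm)
            if sofa is None:
                continue
            rows.extend(frame_sliding_dynamic(adm, outcome, sofa, cfg))
        else:  # on_clinical_demand
            events = event_groups.get(adm.admission_id, empty_events)
            rows.extend(frame_on_clinical_demand(adm, outcome, events, cfg))
    return pd.DataFrame(
        [(s.sample_id, s.admission_id, s.prediction_time, s.label, s.structure) for s in rows],
        columns=SAMPLE_COLUMNS,
    )
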