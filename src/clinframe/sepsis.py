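"""Sepsis-3 onset labeling: suspected infection plus acute SOFA increase.

Suspected infection (SI) is the coherent occurrence, within an admission, of
a culture sample and an antibiotic administration: culture-first pairs
qualify when the antibiotic follows within 72 h, antibiotic-first pairs when
the culture follows within 24 h.  The SI index time is the earlier member of
the pair.

Organ dysfunction is an acute SOFA increase of >= 2 points evaluated inside
the window [index - 48 h, index + 24 h] (clipped to the admission).  "Acute
increase" is measured against the running minimum of the SOFA series within
the window up to the candidate time.  The admission's onset time is the
earliest qualifying grid time over all SI events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .cohort import Admission, Cohort
from .errors import ConfigurationError
from .sofa import SofaSeries, hourly_grid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Sepsis3Config:
    """Windows and threshold of the Sepsis-3 operationalization (hours)."""

    max_culture_to_abx: float = 72.0
    max_abx_to_culture: float = 24.0
    sofa_window_before: float = 48.0
    sofa_window_after: float = 24.0
    sofa_delta_threshold: int = 2

    def __post_init__(self) -> None:
        for name in ("max_culture_to_abx", "max_abx_to_culture", "sofa_window_before", "sofa_window_after"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.sofa_delta_threshold < 1:
            raise ConfigurationError("sofa_delta_threshold must be >= 1")


@dataclass(frozen=True)
class SuspectedInfectionEvent:
    admission_id: str
    culture_time: float
    abx_time: float

    @property
    def index_time(self) -> float:
        return min(self.culture_time, self.abx_time)


@dataclass(frozen=True)
class SepsisOutcome:
    admission_id: str
    onset_time: float | None = None
    si_index_time: float | None = None

    @property
    def positive(self) -> bool:
        return self.onset_time is not None


def detect_suspected_infection(
    events: pd.DataFrame, cfg: Sepsis3Config = Sepsis3Config()
) -> list[SuspectedInfectionEvent]:
    """All qualifying (culture, antibiotic) pairs of one admission.

    Every pair of events is evaluated independently; EWS assessments are
    ignored.  Results are sorted by index time.
    """
    if len(events) == 0:
        return []
    adm_ids = set(events["admission_id"])
    if len(adm_ids) > 1:
        raise ValueError(f"events from multiple admissions: {sorted(adm_ids)}")
    admission_id = str(next(iter(adm_ids)))
    cultures = events.loc[events["kind"] == "culture_sample", "time"].to_numpy(dtype=float)
    abx = events.loc[events["kind"] == "antibiotic_administration", "time"].to_numpy(dtype=float)
    out: list[SuspectedInfectionEvent] = []
    for c in cultures:
        for a in abx:
            if c <= a:
                ok = (a - c) <= cfg.max_culture_to_abx
            else:
                ok = (c - a) <= cfg.max_abx_to_culture
            if ok:
                out.append(SuspectedInfectionEvent(admission_id, float(c), float(a)))
    out.sort(key=lambda e: (e.index_time, e.culture_time, e.abx_time))
    return out


def detect_onset(
    si_events: Iterable[SuspectedInfectionEvent],
    sofa: SofaSeries,
    cfg: Sepsis3Config = Sepsis3Config(),
) -> SepsisOutcome:
    """Earliest grid time with an acute SOFA increase inside any SI window.

    For an SI index time ``i`` the window is ``[i - 48, i + 24]`` clipped to
    the admission grid.  A grid time ``t`` qualifies when
    ``SOFA(t) - min{SOFA(u) : u in window, u <= t} >= threshold``.
    """
    si_events = list(si_events)
    if not si_events:
        return SepsisOutcome(sofa.admission_id)
    best_onset: float | None = None
    best_index: float | None = None
    for si in si_events:
        lo = si.index_time - cfg.sofa_window_before
        hi = si.index_time + cfg.sofa_window_after
        mask = (sofa.times >= lo) & (sofa.times <= hi)
        if not mask.any():
            continue
        scores = sofa.scores[mask].astype(float)
        times = sofa.times[mask]
        delta = scores - np.minimum.accumulate(scores)
        hit = np.nonzero(delta >= cfg.sofa_delta_threshold)[0]
        if len(hit):
            onset = float(times[hit[0]])
            if best_onset is None or onset < best_onset:
                best_onset, best_index = onset, float(si.index_time)
    if best_onset is None:
        return SepsisOutcome(sofa.admission_id, None, float(min(e.index_time for e in si_events)))
    return SepsisOutcome(sofa.admission_id, best_onset, best_index)


SofaProvider = Callable[[Admission], SofaSeries | None]


@dataclass
class CohortLabels:
    """Per-admission outcomes plus the induced cohort prevalence."""

    outcomes: pd.DataFrame  # admission_id, onset_time, si_index_time
    prevalence: float

    def outcome(self, admission_id: str) -> SepsisOutcome:
        row = self.outcomes.loc[self.outcomes["admission_id"] == admission_id]
        if row.empty:
            raise KeyError(admission_id)
        r = row.iloc[0]
        onset = None if pd.isna(r["onset_time"]) else float(r["onset_time"])
        si = None if pd.isna(r["si_index_time"]) else float(r["si_index_time"])
        return SepsisOutcome(str(r["admission_id"]), onset, si)

    def iter_outcomes(self):
        for r in self.outcomes.itertuples(index=False):
            onset = None if pd.isna(r.onset_time) else float(r.onset_time)
            si = None if pd.isna(r.si_index_time) else float(r.si_index_time)
            yield SepsisOutcome(str(r.admission_id), onset, si)


def label_cohort(
    cohort: Cohort,
    cfg: Sepsis3Config = Sepsis3Config(),
    sofa_provider: SofaProvider | None = None,
) -> CohortLabels:
    """Apply the Sepsis-3 labeler to every admission of a (filtered) cohort.

    ``sofa_provider`` maps an admission to its SOFA series; an admission it
    cannot serve is scored as constant 0 (with a warning), which can never
    label positive.
    """
    records = []
    event_groups = {k: g for k, g in cohort.events.groupby("admission_id")}
    for adm in cohort.iter_admissions():
        events = event_groups.get(adm.admission_id)
        if events is None:
            records.append((adm.admission_id, np.nan, np.nan))
            continue
        si = detect_suspected_infection(events, cfg)
        if not si:
            records.append((adm.admission_id, np.nan, np.nan))
            continue
        series = sofa_provider(adm) if sofa_provider is not None else None
        if series is None:
            logger.warning(
                "no SOFA series for admission %s; assuming constant 0", adm.admission_id
            )
            grid = hourly_grid(adm.admit_time, adm.discharge_time)
            series = SofaSeries(adm.admission_id, grid, np.zeros(len(grid), dtype=int))
        outcome = detect_onset(si, series, cfg)
        records.append(
            (
                adm.admission_id,
                np.nan if outcome.onset_time is None else outcome.onset_time,
                np.nan if outcome.si_index_time is None else outcome.si_index_time,
            )
        )
    outcomes = pd.DataFrame(records, columns=["admission_id", "onset_time", "si_index_time"])
    n = len(outcomes)
    prevalence = float(outcomes["onset_time"].notna().sum() / n) if n else 0.0
    logger.info("label_cohort: prevalence %.4f over %d admissions", prevalence, n)
    return CohortLabels(outcomes, prevalence)
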