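"""SOFA (Sequential Organ Failure Assessment) series on an hourly grid.

Two provenance paths exist for a per-admission SOFA series:

* ``sofa_from_table`` — forward-fills precomputed scores (e.g. registry
  extracts or the synthetic generator's ground-truth series) onto the grid;
* ``compute_sofa_series`` — scores raw measurements with a configurable
  per-organ component table.

The default component table covers the organ systems computable from the
packaged 25-parameter general-ward schema: coagulation (platelets), liver
(bilirubin), renal (creatinine) and cardiovascular (mean arterial pressure).
Respiration (needs FiO2) and CNS (needs GCS) are not recorded in this schema
and score 0, per the missing-as-normal convention: a component whose inputs
were never measured contributes no points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Admission
from .errors import CohortValidationError, ConfigurationError
from .schema import DEFAULT_SCHEMA, ParameterSchema

SOFA_MAX = 24


@dataclass(frozen=True)
class SofaSeries:
    """Integer SOFA totals on an hourly grid spanning one admission."""

    admission_id: str
    times: np.ndarray  # ascending, 1-h spacing
    scores: np.ndarray  # ints in [0, 24]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        scores = np.asarray(self.scores, dtype=int)
        if times.shape != scores.shape:
            raise CohortValidationError("SOFA times and scores must have equal length")
        if len(times) and np.any(np.diff(times) <= 0):
            raise CohortValidationError("SOFA grid times must be strictly ascending")
        if len(scores) and (scores.min() < 0 or scores.max() > SOFA_MAX):
            raise CohortValidationError("SOFA scores must lie in [0, 24]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "scores", scores)

    def at(self, t: float) -> int:
        """Step-function value at time ``t`` (last grid point <= t)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            idx = 0
        return int(self.scores[idx])

    def first_time_above(self, threshold: int = 0) -> float | None:
        """Earliest grid time with score strictly above ``threshold``."""
        above = np.nonzero(self.scores > threshold)[0]
        return float(self.times[above[0]]) if len(above) else None


def hourly_grid(admit_time: float, discharge_time: float) -> np.ndarray:
    """Hourly grid covering the admission: admit, admit+1, ..., >= discharge start."""
    n = int(np.floor(discharge_time - admit_time)) + 1
    return admit_time + np.arange(max(n, 1), dtype=float)


def sofa_from_table(
    admission: Admission,
    times: Sequence[float],
    scores: Sequence[int],
) -> SofaSeries:
    """Forward-fill precomputed SOFA scores onto the hourly admission grid.

    Grid points before the first recorded score default to 0 (no observed
    dysfunction).
    """
    times = np.asarray(times, dtype=float)
    scores_arr = np.asarray(scores)
    if len(times) != len(scores_arr):
        raise CohortValidationError("times and scores must have equal length")
    if len(times) and np.any(np.diff(times) <= 0):
        raise CohortValidationError("SOFA input times must be strictly ascending")
    if len(scores_arr) and (
        not np.all(np.isfinite(np.asarray(scores_arr, dtype=float)))
        or np.any(np.asarray(scores_arr, dtype=float) != np.asarray(scores_arr, dtype=int))
        or np.asarray(scores_arr, dtype=int).min() < 0
        or np.asarray(scores_arr, dtype=int).max() > SOFA_MAX
    ):
        raise CohortValidationError("SOFA scores must be integers in [0, 24]")
    grid = hourly_grid(admission.admit_time, admission.discharge_time)
    if len(times) == 0:
        return SofaSeries(admission.admission_id, grid, np.zeros(len(grid), dtype=int))
    idx = np.searchsorted(times, grid, side="right") - 1
    out = np.where(idx >= 0, np.asarray(scores_arr, dtype=int)[np.clip(idx, 0, None)], 0)
    return SofaSeries(admission.admission_id, grid, out.astype(int))


# -- component scoring ------------------------------------------------------

ComponentFn = Callable[[Mapping[str, float]], int]


@dataclass(frozen=True)
class SofaComponent:
    """One organ-system component: inputs and a scoring rule (0-4 points)."""

    name: str
    inputs: tuple[str, ...]
    score: ComponentFn


def _coagulation(v: Mapping[str, float]) -> int:
    plt = v["B-Platelets"]  # 10^9/L
    if plt < 20:
        return 4
    if plt < 50:
        return 3
    if plt < 100:
        return 2
    if plt < 150:
        return 1
    return 0


def _liver(v: Mapping[str, float]) -> int:
    bili = v["P-Bilirubin"]  # umol/L
    if bili > 204:
        return 4
    if bili >= 102:
        return 3
    if bili >= 33:
        return 2
    if bili >= 20:
        return 1
    return 0


def _renal(v: Mapping[str, float]) -> int:
    crea = v["P-Creatinine"]  # umol/L
    if crea > 440:
        return 4
    if crea >= 300:
        return 3
    if crea >= 171:
        return 2
    if crea >= 110:
        return 1
    return 0


def _cardiovascular(v: Mapping[str, float]) -> int:
    # MAP from cuff pressures; vasopressor tiers are not observable on wards
    sbp = v["Systolic blood pressure"]
    dbp = v["Diastolic blood pressure"]
    mean_ap = dbp + (sbp - dbp) / 3.0
    return 1 if mean_ap < 70 else 0


DEFAULT_SOFA_COMPONENTS: tuple[SofaComponent, ...] = (
    SofaComponent("coagulation", ("B-Platelets",), _coagulation),
    SofaComponent("liver", ("P-Bilirubin",), _liver),
    SofaComponent("renal", ("P-Creatinine",), _renal),
    SofaComponent(
        "cardiovascular", ("Systolic blood pressure", "Diastolic blood pressure"), _cardiovascular
    ),
)


def compute_sofa_series(
    admission: Admission,
    measurements: pd.DataFrame,
    components: Sequence[SofaComponent] = DEFAULT_SOFA_COMPONENTS,
    schema: ParameterSchema = DEFAULT_SCHEMA,
) -> SofaSeries:
    """Score raw measurements of one admission into an hourly SOFA series.

    At each grid hour the most recent value of every input parameter is
    forward-filled; a component with any input still unobserved contributes
    0 points (missing-as-normal).
    """
    for comp in components:
        unknown = [p for p in comp.inputs if p not in schema]
        if unknown:
            raise ConfigurationError(
                f"SOFA component {comp.name!r} references unknown parameters: {unknown}"
            )
    grid = hourly_grid(admission.admit_time, admission.discharge_time)
    total = np.zeros(len(grid), dtype=int)

    needed = sorted({p for comp in components for p in comp.inputs})
    filled: dict[str, np.ndarray] = {}
    for param in needed:
        rows = measurements.loc[measurements["parameter"] == param]
        if rows.empty:
            continue
        t = rows["time"].to_numpy(dtype=float)
        v = rows["value"].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        idx = np.searchsorted(t, grid, side="right") - 1
        vals = np.full(len(grid), np.nan)
        have = idx >= 0
        vals[have] = v[np.clip(idx, 0, None)[have]]
        filled[param] = vals

    for comp in components:
        if any(p not in filled for p in comp.inputs):
            continue  # never measured -> 0 points throughout
        stacked = np.vstack([filled[p] for p in comp.inputs])
        ok = ~np.isnan(stacked).any(axis=0)
        pts = np.zeros(len(grid), dtype=int)
        for i in np.nonzero(ok)[0]:
            pts[i] = comp.score({p: stacked[j, i] for j, p in enumerate(comp.inputs)})
        total += pts

    return SofaSeries(admission.admission_id, grid, np.clip(total, 0, SOFA_MAX))


def sofa_provider_from_table(cohort, sofa_table: pd.DataFrame):
    """Build a per-admission SOFA provider from a long table
    (admission_id, time, score).  Admissions absent from the table map to None.
    """
    groups = {k: g for k, g in sofa_table.groupby("admission_id")}

    def provider(admission: Admission) -> SofaSeries | None:
        g = groups.get(admission.admission_id)
        if g is None:
            return None
        g = g.sort_values("time", kind="stable")
        return sofa_from_table(
            admission, g["time"].to_numpy(dtype=float), g["score"].to_numpy(dtype=int)
        )

    return provider
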