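"""Longitudinal cohort container, CSV interchange, and the length-of-stay filter.

A cohort is three long-format tables:

* ``admissions``:   admission_id, patient_id, admit_time, discharge_time
* ``measurements``: admission_id, time, parameter, value
* ``events``:       admission_id, time, kind

All times are continuous hours relative to an arbitrary per-cohort epoch.
Windows throughout the package are half-open intervals ``(a, b]`` so a
boundary observation belongs to exactly one window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortSchemaError, CohortValidationError, ReferentialIntegrityError
from .schema import DEFAULT_SCHEMA, ParameterSchema

logger = logging.getLogger(__name__)

EVENT_KINDS = frozenset({"antibiotic_administration", "culture_sample", "ews_assessment"})

ADMISSION_COLUMNS = ["admission_id", "patient_id", "admit_time", "discharge_time"]
MEASUREMENT_COLUMNS = ["admission_id", "time", "parameter", "value"]
EVENT_COLUMNS = ["admission_id", "time", "kind"]


@dataclass(frozen=True)
class Admission:
    """One inpatient stay."""

    admission_id: str
    patient_id: str
    admit_time: float
    discharge_time: float

    @property
    def los_hours(self) -> float:
        return self.discharge_time - self.admit_time


@dataclass
class Cohort:
    """In-memory cohort with referential integrity between the three tables."""

    admissions: pd.DataFrame
    measurements: pd.DataFrame
    events: pd.DataFrame
    schema: ParameterSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name, df, cols in (
            ("admissions", self.admissions, ADMISSION_COLUMNS),
            ("measurements", self.measurements, MEASUREMENT_COLUMNS),
            ("events", self.events, EVENT_COLUMNS),
        ):
            for col in cols:
                if col not in df.columns:
                    raise CohortSchemaError(f"{name} table is missing required column {col!r}")

        adm = self.admissions
        if adm["admission_id"].duplicated().any():
            dupes = sorted(adm.loc[adm["admission_id"].duplicated(), "admission_id"].unique())
            raise CohortValidationError(f"duplicate admission_id values: {dupes}")
        for col in ("admit_time", "discharge_time"):
            if not np.isfinite(adm[col].to_numpy(dtype=float)).all():
                raise CohortValidationError(f"non-finite values in admissions.{col}")
        bad_los = adm["discharge_time"].to_numpy() <= adm["admit_time"].to_numpy()
        if bad_los.any():
            ids = sorted(adm.loc[bad_los, "admission_id"])
            raise CohortValidationError(f"discharge_time must exceed admit_time for: {ids}")
        # one patient per admission is structural (a row has one patient_id);
        # patients may of course have several admissions.

        known = set(adm["admission_id"])
        for name, df in (("measurements", self.measurements), ("events", self.events)):
            dangling = sorted(set(df["admission_id"]) - known)
            if dangling:
                raise ReferentialIntegrityError(
                    f"{name} reference unknown admission_id values: {dangling}"
                )

        meas = self.measurements
        if len(meas):
            unknown = sorted(set(meas["parameter"]) - set(self.schema.names))
            if unknown:
                raise CohortValidationError(f"unknown parameter names: {unknown}")
            if not np.isfinite(meas["value"].to_numpy(dtype=float)).all():
                bad = meas.index[~np.isfinite(meas["value"].to_numpy(dtype=float))].tolist()
                raise CohortValidationError(f"non-finite measurement values at rows {bad}")
            self._check_times_in_admission(meas, "measurements")

        ev = self.events
        if len(ev):
            bad_kind = sorted(set(ev["kind"]) - EVENT_KINDS)
            if bad_kind:
                raise CohortValidationError(f"unknown event kinds: {bad_kind}")
            self._check_times_in_admission(ev, "events")

        # canonical ordering: by admission then time
        self.admissions = adm.sort_values("admission_id", kind="stable").reset_index(drop=True)
        self.measurements = meas.sort_values(
            ["admission_id", "time"], kind="stable"
        ).reset_index(drop=True)
        self.events = ev.sort_values(["admission_id", "time"], kind="stable").reset_index(
            drop=True
        )

    def _check_times_in_admission(self, df: pd.DataFrame, name: str) -> None:
        adm = self.admissions.set_index("admission_id")
        admit = adm["admit_time"].reindex(df["admission_id"]).to_numpy(dtype=float)
        disch = adm["discharge_time"].reindex(df["admission_id"]).to_numpy(dtype=float)
        t = df["time"].to_numpy(dtype=float)
        if not np.isfinite(t).all():
            raise CohortValidationError(f"non-finite times in {name}")
        outside = (t < admit) | (t > disch)
        if outside.any():
            rows = df.index[outside].tolist()[:20]
            raise CohortValidationError(
                f"{name} rows with time outside their admission interval (rows {rows})"
            )

    # -- convenience --------------------------------------------------------

    @property
    def n_admissions(self) -> int:
        return len(self.admissions)

    def iter_admissions(self):
        for row in self.admissions.itertuples(index=False):
            yield Admission(
                str(row.admission_id),
                str(row.patient_id),
                float(row.admit_time),
                float(row.discharge_time),
            )

    def admission(self, admission_id: str) -> Admission:
        row = self.admissions.loc[self.admissions["admission_id"] == admission_id]
        if row.empty:
            raise KeyError(admission_id)
        r = row.iloc[0]
        return Admission(
            str(r["admission_id"]), str(r["patient_id"]), float(r["admit_time"]), float(r["discharge_time"])
        )

    def measurements_for(self, admission_id: str) -> pd.DataFrame:
        return self.measurements.loc[self.measurements["admission_id"] == admission_id]

    def events_for(self, admission_id: str) -> pd.DataFrame:
        return self.events.loc[self.events["admission_id"] == admission_id]


# -- I/O --------------------------------------------------------------------


def _read_table(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    df = pd.read_csv(
        path,
        dtype={"admission_id": str, "patient_id": str, "parameter": str, "kind": str},
        float_precision="round_trip",
    )
    for col in required:
        if col not in df.columns:
            raise CohortSchemaError(f"{name} table {path} is missing required column {col!r}")
    numeric = [c for c in required if c in ("admit_time", "discharge_time", "time", "value")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()[:20]
            raise CohortValidationError(
                f"{name} table {path}: unparseable numeric {col!r} at rows {rows}"
            )
        if coerced.isna().any():
            rows = df.index[coerced.isna()].tolist()[:20]
            raise CohortValidationError(f"{name} table {path}: missing {col!r} at rows {rows}")
        df[col] = coerced.astype(float)
    return df[required]


def read_cohort(
    admissions_path: str | Path,
    measurements_path: str | Path,
    events_path: str | Path,
    schema: ParameterSchema = DEFAULT_SCHEMA,
) -> Cohort:
    """Load a cohort from the three-table CSV interchange format."""
    adm = _read_table(admissions_path, ADMISSION_COLUMNS, "admissions")
    meas = _read_table(measurements_path, MEASUREMENT_COLUMNS, "measurements")
    ev = _read_table(events_path, EVENT_COLUMNS, "events")
    return Cohort(adm, meas, ev, schema)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the three cohort tables to ``directory``; returns the file paths.

    Round-trip contract: ``read_cohort(*write_cohort(c).values())`` reproduces
    the cohort up to row order (floats survive via repr-exact CSV encoding).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "admissions": directory / "admissions.csv",
        "measurements": directory / "measurements.csv",
        "events": directory / "events.csv",
    }
    try:
        # %.17g round-trips any IEEE double exactly
        cohort.admissions.to_csv(paths["admissions"], index=False, float_format="%.17g")
        cohort.measurements.to_csv(paths["measurements"], index=False, float_format="%.17g")
        cohort.events.to_csv(paths["events"], index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"failed writing cohort to {directory}: {exc}") from exc
    return paths


# -- inclusion filter -------------------------------------------------------


def filter_admissions(
    cohort: Cohort, min_los_hours: float = 24.0, max_los_days: float = 50.0
) -> Cohort:
    """Apply the length-of-stay inclusion filter.

    Retains admissions with ``min_los_hours <= LOS <= max_los_days * 24``;
    the bounds are read strictly ("shorter than" / "longer than"), so stays of
    exactly 24 h or exactly 50 days are retained.  Measurements and events of
    dropped admissions are removed.  Idempotent.
    """
    adm = cohort.admissions
    los = adm["discharge_time"].to_numpy() - adm["admit_time"].to_numpy()
    keep = (los >= min_los_hours) & (los <= max_los_days * 24.0)
    dropped = int((~keep).sum())
    logger.info(
        "filter_admissions: dropped %d of %d admissions (LOS outside [%g h, %g d])",
        dropped,
        len(adm),
        min_los_hours,
        max_los_days,
    )
    kept_ids = set(adm.loc[keep, "admission_id"])
    return Cohort(
        adm.loc[keep].reset_index(drop=True),
        cohort.measurements.loc[
            cohort.measurements["admission_id"].isin(kept_ids)
        ].reset_index(drop=True),
        cohort.events.loc[cohort.events["admission_id"].isin(kept_ids)].reset_index(drop=True),
        cohort.schema,
    )


def empty_cohort(schema: ParameterSchema = DEFAULT_SCHEMA) -> Cohort:
    return Cohort(
        pd.DataFrame(columns=ADMISSION_COLUMNS).astype(
            {"admit_time": float, "discharge_time": float}
        ),
        pd.DataFrame(columns=MEASUREMENT_COLUMNS).astype({"time": float, "value": float}),
        pd.DataFrame(columns=EVENT_COLUMNS).astype({"time": float}),
        schema,
    )
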