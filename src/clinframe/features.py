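"""Observation-window featurization: 12 h -> two 6-h timesteps -> 50 features.

Per sample, measurements in the half-open window ``(t - 12, t]`` (t = the
prediction time) are averaged within 1-h bins anchored at t, the hourly
values are pooled into an early (hours -12..-6) and a late (hours -6..0)
timestep, a forward/backward imputation fills a one-sided gap from the other
timestep, and the feature vector is the 25 late-timestep values plus the 25
timestep differences (delta = late - early).  Residual missingness is kept
as NaN; model adapters decide how to consume it.

``featurize_samples`` is a vectorized batch driver; the step functions
(`extract_observation`, `hourly_mean`, `bin_timesteps`,
`impute_forward_backward`, `assemble_features`) form the reference per-sample
path and the batch driver must agree with their composition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .schema import DEFAULT_SCHEMA, ParameterSchema

_EPS = 1e-9


@dataclass
class TimestepGrid:
    """Per-parameter values for the two 6-h timesteps; NaN marks missing."""

    sample_id: str
    parameters: list[str]
    early: np.ndarray  # shape (n_params,)
    late: np.ndarray


@dataclass
class FeatureVector:
    sample_id: str
    names: list[str]  # 2 * n_params entries: values then deltas
    values: np.ndarray


def feature_names(schema: ParameterSchema = DEFAULT_SCHEMA) -> list[str]:
    return list(schema.names) + [f"{n} delta" for n in schema.names]


def extract_observation(
    measurements: pd.DataFrame, prediction_time: float, observation_window: float = 12.0
) -> pd.DataFrame:
    """Measurements with time in ``(prediction_time - window, prediction_time]``.

    Nothing after the prediction time can ever enter a feature (leakage guard).
    """
    t = measurements["time"].to_numpy(dtype=float)
    mask = (t > prediction_time - observation_window) & (t <= prediction_time)
    return measurements.loc[mask]


def hourly_mean(
    window: pd.DataFrame, prediction_time: float, observation_window: float = 12.0
) -> pd.DataFrame:
    """Collapse same-hour repeats to their arithmetic mean.

    Hour bins are anchored at the prediction time and counted backwards:
    bin h covers ``(t - h - 1, t - h]``; bin 0 is the most recent hour.
    Returns a table (parameter, hour, value).
    """
    if len(window) == 0:
        return pd.DataFrame(columns=["parameter", "hour", "value"])
    t = window["time"].to_numpy(dtype=float)
    hour = np.floor(prediction_time - t).astype(int)
    hour = np.clip(hour, 0, int(np.ceil(observation_window)) - 1)
    df = pd.DataFrame(
        {"parameter": window["parameter"].to_numpy(), "hour": hour, "value": window["value"].to_numpy(dtype=float)}
    )
    out = df.groupby(["parameter", "hour"], as_index=False)["value"].mean()
    return out


def bin_timesteps(
    hourly: pd.DataFrame,
    sample_id: str = "",
    schema: ParameterSchema = DEFAULT_SCHEMA,
    observation_window: float = 12.0,
) -> TimestepGrid:
    """Pool hourly values into the early/late 6-h timesteps (mean of the
    available hourly means; all-missing pools stay missing)."""
    half = observation_window / 2.0
    names = schema.names
    early = np.full(len(names), np.nan)
    late = np.full(len(names), np.nan)
    if len(hourly):
        idx = {n: i for i, n in enumerate(names)}
        late_df = hourly.loc[hourly["hour"] < half].groupby("parameter")["value"].mean()
        early_df = hourly.loc[hourly["hour"] >= half].groupby("parameter")["value"].mean()
        for p, v in late_df.items():
            late[idx[p]] = v
        for p, v in early_df.items():
            early[idx[p]] = v
    return TimestepGrid(sample_id, list(names), early, late)


def impute_forward_backward(grid: TimestepGrid) -> TimestepGrid:
    """Fill a missing late value from early (forward), then a missing early
    value from late (backward).  Both-missing stays missing.  Idempotent."""
    early = grid.early.copy()
    late = grid.late.copy()
    fwd = np.isnan(late) & ~np.isnan(early)
    late[fwd] = early[fwd]
    bwd = np.isnan(early) & ~np.isnan(late)
    early[bwd] = late[bwd]
    return TimestepGrid(grid.sample_id, grid.parameters, early, late)


def assemble_features(grid: TimestepGrid) -> FeatureVector:
    """Values = late timestep; deltas = late - early.  2 x |schema| slots."""
    names = list(grid.parameters) + [f"{n} delta" for n in grid.parameters]
    values = np.concatenate([grid.late, grid.late - grid.early])
    return FeatureVector(grid.sample_id, names, values)


def featurize_sample(
    measurements: pd.DataFrame,
    prediction_time: float,
    sample_id: str = "",
    schema: ParameterSchema = DEFAULT_SCHEMA,
    observation_window: float = 12.0,
) -> FeatureVector:
    """Reference per-sample path: compose the five pipeline steps."""
    window = extract_observation(measurements, prediction_time, observation_window)
    hourly = hourly_mean(window, prediction_time, observation_window)
    grid = bin_timesteps(hourly, sample_id, schema, observation_window)
    grid = impute_forward_backward(grid)
    return assemble_features(grid)


def featurize_samples(
    cohort: Cohort,
    samples: pd.DataFrame,
    observation_window: float = 12.0,
) -> pd.DataFrame:
    """Vectorized batch featurization of a samples table.

    Returns a frame indexed like ``samples`` with columns
    ``sample_id, label`` followed by the 50 feature columns (NaN = missing).
    """
    schema = cohort.schema
    names = schema.names
    n_params = len(names)
    n_bins = int(np.ceil(observation_window))
    half = observation_window / 2.0
    p_index = {n: i for i, n in enumerate(names)}

    n = len(samples)
    early = np.full((n, n_params), np.nan)
    late = np.full((n, n_params), np.nan)

    meas_by_adm = {k: g for k, g in cohort.measurements.groupby("admission_id")}
    for adm_id, s_idx in samples.groupby("admission_id").indices.items():
        g = meas_by_adm.get(adm_id)
        if g is None:
            continue
        t_pred = samples["prediction_time"].to_numpy(dtype=float)[s_idx]
        for param, rows in g.groupby("parameter"):
            j = p_index[param]
            mt = rows["time"].to_numpy(dtype=float)
            mv = rows["value"].to_numpy(dtype=float)
            # (n_samples, n_meas) hour-bin matrix; same boundary predicates
            # as extract_observation / hourly_mean
            valid = (mt[None, :] > (t_pred[:, None] - observation_window)) & (
                mt[None, :] <= t_pred[:, None]
            )
            binm = np.floor(t_pred[:, None] - mt[None, :]).astype(int)
            binm = np.clip(binm, 0, n_bins - 1)
            flat = (np.arange(len(s_idx))[:, None] * n_bins + binm)[valid]
            sums = np.bincount(
                flat,
                weights=np.broadcast_to(mv[None, :], valid.shape)[valid],
                minlength=len(s_idx) * n_bins,
            )
            cnts = np.bincount(flat, minlength=len(s_idx) * n_bins)
            with np.errstate(invalid="ignore"):
                hmean = (sums / cnts).reshape(len(s_idx), n_bins)
            late_mask = np.arange(n_bins) < half
            for half_mask, target in ((late_mask, late), (~late_mask, early)):
                vals = hmean[:, half_mask]
                cnt = (~np.isnan(vals)).sum(axis=1)
                total = np.nansum(vals, axis=1)
                target[s_idx, j] = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)

    # forward/backward imputation between the two timesteps
    fwd = np.isnan(late) & ~np.isnan(early)
    late[fwd] = early[fwd]
    bwd = np.isnan(early) & ~np.isnan(late)
    early[bwd] = late[bwd]

    cols = feature_names(schema)
    out = pd.DataFrame(np.hstack([late, late - early]), columns=cols, index=samples.index)
    out.insert(0, "label", samples["label"].to_numpy(dtype=int))
    out.insert(0, "sample_id", samples["sample_id"].to_numpy())
    return out


def missingness_report(features_by_structure: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Percent of samples missing per feature, per framing structure.

    Delta features appear as their own rows, mirroring how ward vital-sign
    missingness is usually tabulated.
    """
    frames = {}
    for structure, feats in features_by_structure.items():
        cols = [c for c in feats.columns if c not in ("sample_id", "label")]
        if len(feats) == 0:
            frames[structure] = pd.Series(np.nan, index=cols)
        else:
            frames[structure] = feats[cols].isna().mean() * 100.0
    out = pd.DataFrame(frames)
    out.index.name = "parameter"
    return out
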