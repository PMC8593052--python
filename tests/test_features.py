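import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import clinframe as cf
from clinframe.schema import LAB, Parameter, ParameterSchema


def meas(rows):
    return pd.DataFrame(rows, columns=["admission_id", "time", "parameter", "value"])


# -- observation extraction -------------------------------------------------


def test_extract_observation_boundaries():
    m = meas(
        [
            ("A1", 7.9, "Pulse", 1.0),   # before window start (t - 12 = 8)
            ("A1", 8.0, "Pulse", 2.0),   # exactly at open lower bound -> excluded
            ("A1", 8.1, "Pulse", 3.0),
            ("A1", 20.0, "Pulse", 4.0),  # exactly at prediction time -> included
            ("A1", 20.1, "Pulse", 5.0),  # after prediction time -> excluded
        ]
    )
    window = cf.extract_observation(m, prediction_time=20.0)
    assert window["value"].tolist() == [3.0, 4.0]


def test_hourly_mean_collapses_same_hour_values():
    m = meas([("A1", 19.2, "Pulse", 80.0), ("A1", 19.9, "Pulse", 90.0)])
    hourly = cf.hourly_mean(m, prediction_time=20.0)
    assert hourly["value"].tolist() == [85.0]
    assert hourly["hour"].tolist() == [0]


def test_hourly_mean_single_value_identity_and_empty_bins():
    m = meas([("A1", 15.5, "Pulse", 72.0)])
    hourly = cf.hourly_mean(m, prediction_time=20.0)
    assert hourly["value"].tolist() == [72.0]
    assert hourly["hour"].tolist() == [4]


# -- timestep binning and imputation ----------------------------------------


def test_bin_timesteps_late_half_only():
    hourly = pd.DataFrame({"parameter": ["Pulse"] * 3, "hour": [0, 1, 2], "value": [1.0, 2.0, 3.0]})
    grid = cf.bin_timesteps(hourly)
    i = grid.parameters.index("Pulse")
    assert grid.late[i] == 2.0
    assert np.isnan(grid.early[i])


def test_bin_timesteps_constant_everywhere():
    hourly = pd.DataFrame(
        {"parameter": ["Pulse"] * 12, "hour": list(range(12)), "value": [7.0] * 12}
    )
    grid = cf.bin_timesteps(hourly)
    i = grid.parameters.index("Pulse")
    assert grid.early[i] == 7.0 and grid.late[i] == 7.0


def test_bin_timesteps_empty():
    grid = cf.bin_timesteps(pd.DataFrame(columns=["parameter", "hour", "value"]))
    assert np.isnan(grid.early).all() and np.isnan(grid.late).all()


@pytest.mark.parametrize(
    "early,late,expect_early,expect_late",
    [(7.0, np.nan, 7.0, 7.0), (np.nan, 5.0, 5.0, 5.0), (np.nan, np.nan, np.nan, np.nan)],
)
def test_forward_backward_imputation(early, late, expect_early, expect_late):
    schema = cf.DEFAULT_SCHEMA
    e = np.full(len(schema), np.nan)
    l = np.full(len(schema), np.nan)
    e[0], l[0] = early, late
    grid = cf.impute_forward_backward(cf.TimestepGrid("s", schema.names, e, l))
    assert (grid.early[0] == expect_early) or (np.isnan(grid.early[0]) and np.isnan(expect_early))
    assert (grid.late[0] == expect_late) or (np.isnan(grid.late[0]) and np.isnan(expect_late))


@given(
    early=st.lists(st.one_of(st.none(), st.floats(-100, 100)), min_size=25, max_size=25),
    late=st.lists(st.one_of(st.none(), st.floats(-100, 100)), min_size=25, max_size=25),
)
@settings(max_examples=100, derandomize=True)
def test_imputation_idempotent_and_delta_zero_for_single_source(early, late):
    e = np.array([np.nan if v is None else v for v in early])
    l = np.array([np.nan if v is None else v for v in late])
    grid = cf.TimestepGrid("s", cf.DEFAULT_SCHEMA.names, e.copy(), l.copy())
    once = cf.impute_forward_backward(grid)
    twice = cf.impute_forward_backward(once)
    np.testing.assert_array_equal(once.early, twice.early)
    np.testing.assert_array_equal(once.late, twice.late)
    fv = cf.assemble_features(once)
    single_source = (np.isnan(e) ^ np.isnan(l))
    deltas = fv.values[25:]
    assert np.all(deltas[single_source] == 0.0)


# -- feature assembly -------------------------------------------------------


def test_assemble_features_values_and_deltas():
    schema = cf.DEFAULT_SCHEMA
    e = np.full(len(schema), np.nan)
    l = np.full(len(schema), np.nan)
    e[0], l[0] = 4.0, 10.0
    fv = cf.assemble_features(cf.TimestepGrid("s", schema.names, e, l))
    assert fv.values[0] == 10.0
    assert fv.values[25] == 6.0
    assert len(fv.values) == 50


@pytest.mark.parametrize("size", [1, 3, 25])
def test_feature_count_doubles_schema(size):
    params = tuple(Parameter(f"X{i}", "u", LAB) for i in range(size))
    schema = ParameterSchema(params)
    grid = cf.bin_timesteps(
        pd.DataFrame(columns=["parameter", "hour", "value"]), schema=schema
    )
    fv = cf.assemble_features(grid)
    assert len(fv.values) == 2 * size
    assert len(cf.feature_names(schema)) == 2 * size


def test_packaged_schema_yields_exactly_50_features(tiny_cohort):
    samples = pd.DataFrame(
        {
            "sample_id": ["s1"],
            "admission_id": ["A1"],
            "prediction_time": [20.0],
            "label": [0],
            "structure": ["sliding_window"],
        }
    )
    feats = cf.featurize_samples(tiny_cohort, samples)
    assert feats.shape == (1, 52)  # sample_id + label + 50 features


# -- batch/reference agreement ----------------------------------------------


def test_batch_featurization_matches_reference_path(synth200, synth200_labels):
    labels, provider = synth200_labels
    cohort = synth200.cohort
    cfg = cf.FramingConfig(structure="sliding_window")
    samples = cf.frame_cohort(cohort, labels, cfg).head(300)
    batch = cf.featurize_samples(cohort, samples)
    cols = [c for c in batch.columns if c not in ("sample_id", "label")]
    for row_idx in range(0, len(samples), 29):
        s = samples.iloc[row_idx]
        fv = cf.featurize_sample(
            cohort.measurements_for(s["admission_id"]), s["prediction_time"], s["sample_id"]
        )
        np.testing.assert_allclose(
            batch.iloc[row_idx][cols].to_numpy(dtype=float), fv.values, equal_nan=True, rtol=0, atol=0
        )


def test_poisoning_future_measurements_changes_no_feature(synth200, synth200_labels):
    """Leakage guard: data after the prediction time never enters features."""
    labels, provider = synth200_labels
    cohort = synth200.cohort
    cfg = cf.FramingConfig(structure="sliding_window")
    samples = cf.frame_cohort(cohort, labels, cfg)
    samples = samples.sample(n=200, random_state=1).reset_index(drop=True)
    clean = cf.featurize_samples(cohort, samples)

    pred_by_adm = samples.groupby("admission_id")["prediction_time"].min()
    meas = cohort.measurements.copy()
    cutoff = meas["admission_id"].map(pred_by_adm)
    poisonable = cutoff.notna() & (meas["time"] > cutoff)
    meas.loc[poisonable, "value"] = 9.9e5
    # bypass value-range realism but keep structural validity
    poisoned_cohort = cf.Cohort(cohort.admissions, meas, cohort.events, cohort.schema)

    # only compare samples whose prediction time is the admission minimum:
    # for those, every poisoned row lies strictly in their future
    first = samples[samples["prediction_time"] == samples["admission_id"].map(pred_by_adm)]
    poisoned = cf.featurize_samples(poisoned_cohort, first)
    cols = [c for c in clean.columns if c not in ("sample_id", "label")]
    np.testing.assert_array_equal(
        clean.loc[first.index, cols].to_numpy(), poisoned[cols].to_numpy()
    )
    assert int(poisonable.sum()) > 1000  # the poison actually touched plenty of rows


# -- missingness ------------------------------------------------------------


def test_missingness_report_extremes(tiny_cohort):
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "admission_id": ["A1", "A1"],
            "prediction_time": [13.0, 30.0],
            "label": [0, 0],
            "structure": ["sliding_window"] * 2,
        }
    )
    feats = cf.featurize_samples(tiny_cohort, samples)
    rep = cf.missingness_report({"sliding_window": feats})
    assert rep.loc["P(aB)-Lactate", "sliding_window"] == 100.0  # never measured
    assert set(rep["sliding_window"].unique()) <= set(np.arange(0.0, 100.5, 50.0))


def test_demand_framing_sees_less_vital_missingness(synth200, synth200_labels):
    labels, provider = synth200_labels
    cohort = synth200.cohort
    feats = {}
    for s in ("sliding_window", "on_clinical_demand"):
        cfg = cf.FramingConfig(structure=s)
        samples = cf.frame_cohort(cohort, labels, cfg, sofa_provider=provider)
        feats[s] = cf.featurize_samples(cohort, samples)
    rep = cf.missingness_report(feats)
    for vital in cohort.schema.vitals:
        assert rep.loc[vital, "on_clinical_demand"] < rep.loc[vital, "sliding_window"]
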