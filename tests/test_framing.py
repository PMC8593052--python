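import numpy as np
import pandas as pd
import pytest

import clinframe as cf
from clinframe.errors import ConfigurationError

from conftest import make_admission
from oracles import sliding_samples_oracle


def outcome(admission_id="A1", onset=None, si=None):
    return cf.SepsisOutcome(admission_id, onset, si)


CFG = dict(observation_window=12.0, prediction_window=12.0, lead_window=0.0, window_shift=6.0)


def fixed_cfg(seed=0):
    return cf.FramingConfig(structure="fixed_time_to_onset", onset_offset=12.0, seed=seed, **CFG)


def sliding_cfg():
    return cf.FramingConfig(structure="sliding_window", **CFG)


# -- fixed time to onset ----------------------------------------------------


def test_fixed_positive_sample_at_offset_before_onset():
    adm = make_admission(discharge=60.0)
    rng = np.random.default_rng(0)
    samples = cf.frame_fixed_time_to_onset(adm, outcome(onset=40.0), fixed_cfg(), rng)
    assert len(samples) == 1
    assert samples[0].prediction_time == 28.0
    assert samples[0].label == 1


def test_fixed_early_onset_yields_no_sample():
    adm = make_admission(discharge=60.0)
    rng = np.random.default_rng(0)
    assert cf.frame_fixed_time_to_onset(adm, outcome(onset=6.0), fixed_cfg(), rng) == []


def test_fixed_negative_time_reproducible_across_runs():
    adm = make_admission(discharge=60.0)
    a = cf.frame_fixed_time_to_onset(adm, outcome(), fixed_cfg(), np.random.default_rng(7))
    b = cf.frame_fixed_time_to_onset(adm, outcome(), fixed_cfg(), np.random.default_rng(7))
    assert a[0].prediction_time == b[0].prediction_time
    assert a[0].label == 0
    assert adm.admit_time < a[0].prediction_time <= adm.discharge_time


def test_fixed_emits_at_most_one_sample_per_admission(synth200, synth200_labels):
    labels, provider = synth200_labels
    samples = cf.frame_cohort(synth200.cohort, labels, fixed_cfg())
    assert samples.groupby("admission_id").size().max() == 1


# -- sliding window ---------------------------------------------------------


def test_sliding_negative_48h_admission_grid():
    adm = make_admission(discharge=48.0)
    samples = cf.frame_sliding_window(adm, outcome(), sliding_cfg())
    assert [s.prediction_time for s in samples] == [12.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0]
    assert all(s.label == 0 for s in samples)


def test_sliding_positive_onset_30_labels_and_censoring():
    adm = make_admission(discharge=48.0)
    samples = cf.frame_sliding_window(adm, outcome(onset=30.0), sliding_cfg())
    assert [(s.prediction_time, s.label) for s in samples] == [(12.0, 0), (18.0, 1), (24.0, 1)]


def test_sliding_admission_shorter_than_observation_window():
    adm = make_admission(discharge=11.0)
    assert cf.frame_sliding_window(adm, outcome(), sliding_cfg()) == []


def test_onset_exactly_at_prediction_window_end_is_positive():
    adm = make_admission(discharge=48.0)
    samples = cf.frame_sliding_window(adm, outcome(onset=24.0), sliding_cfg())
    by_time = {s.prediction_time: s.label for s in samples}
    assert by_time[12.0] == 1  # 24 in (12, 24]


def test_sliding_matches_enumeration_oracle_on_random_admissions():
    rng = np.random.default_rng(123)
    cfg_pool = [
        cf.FramingConfig(structure="sliding_window", observation_window=o, prediction_window=p,
                         lead_window=l, window_shift=s)
        for o, p, l, s in [(12, 12, 0, 6), (12, 12, 3, 6), (6, 8, 0, 4), (12, 24, 0, 8)]
    ]
    for _ in range(1000):
        cfg = cfg_pool[int(rng.integers(len(cfg_pool)))]
        admit = float(np.round(rng.uniform(0, 100), 2))
        discharge = admit + float(np.round(rng.uniform(24, 300), 2))
        adm = make_admission(admit=admit, discharge=discharge)
        onset = None
        if rng.random() < 0.5:
            onset = admit + float(np.round(rng.uniform(1, discharge - admit), 2))
        samples = cf.frame_sliding_window(adm, outcome(onset=onset), cfg)
        expected = sliding_samples_oracle(
            admit,
            discharge,
            onset,
            cfg.observation_window,
            cfg.prediction_window,
            cfg.lead_window,
            cfg.window_shift,
        )
        assert [(s.prediction_time, s.label) for s in samples] == expected


# -- dynamic inclusion ------------------------------------------------------


def test_dynamic_zero_sofa_yields_no_samples():
    adm = make_admission(discharge=48.0)
    sofa = cf.sofa_from_table(adm, [0.0], [0])
    assert cf.frame_sliding_dynamic(adm, outcome(), sofa, sliding_cfg()) == []


def test_dynamic_equals_sliding_when_criterion_met_from_start():
    adm = make_admission(discharge=48.0)
    sofa = cf.sofa_from_table(adm, [0.0], [1])
    dyn = cf.frame_sliding_dynamic(adm, outcome(onset=30.0), sofa, sliding_cfg())
    base = cf.frame_sliding_window(adm, outcome(onset=30.0), sliding_cfg())
    assert [(s.prediction_time, s.label) for s in dyn] == [
        (s.prediction_time, s.label) for s in base
    ]


def test_dynamic_starts_at_first_grid_time_after_inclusion():
    adm = make_admission(discharge=48.0)
    sofa = cf.sofa_from_table(adm, [0.0, 20.0], [0, 1])
    dyn = cf.frame_sliding_dynamic(adm, outcome(), sofa, sliding_cfg())
    assert [s.prediction_time for s in dyn] == [24.0, 30.0, 36.0, 42.0, 48.0]


def test_dynamic_subset_with_identical_positives(synth200, synth200_labels):
    labels, provider = synth200_labels
    cohort = synth200.cohort
    dyn_cfg = cf.FramingConfig(structure="sliding_window_dynamic", **CFG)
    dyn = cf.frame_cohort(cohort, labels, dyn_cfg, sofa_provider=provider)
    base = cf.frame_cohort(cohort, labels, sliding_cfg())
    dyn_keys = set(zip(dyn["admission_id"], dyn["prediction_time"], dyn["label"]))
    base_keys = set(zip(base["admission_id"], base["prediction_time"], base["label"]))
    assert dyn_keys <= base_keys
    dyn_pos = {k for k in dyn_keys if k[2] == 1}
    base_pos = {k for k in base_keys if k[2] == 1}
    assert dyn_pos == base_pos
    assert len(dyn) < len(base)


# -- on clinical demand -----------------------------------------------------


def ews_events(times):
    return pd.DataFrame(
        {"admission_id": ["A1"] * len(times), "time": times, "kind": ["ews_assessment"] * len(times)}
    )


def demand_cfg():
    return cf.FramingConfig(structure="on_clinical_demand", **CFG)


def test_demand_one_sample_per_assessment():
    adm = make_admission(discharge=48.0)
    samples = cf.frame_on_clinical_demand(adm, outcome(), ews_events([5.0, 17.5, 40.0]), demand_cfg())
    assert [(s.prediction_time, s.label) for s in samples] == [(5.0, 0), (17.5, 0), (40.0, 0)]


def test_demand_positive_label_interval_membership():
    adm = make_admission(discharge=48.0)
    samples = cf.frame_on_clinical_demand(
        adm, outcome(onset=28.0), ews_events([20.0]), demand_cfg()
    )
    assert [(s.prediction_time, s.label) for s in samples] == [(20.0, 1)]


def test_demand_no_events_no_samples():
    adm = make_admission(discharge=48.0)
    assert cf.frame_on_clinical_demand(adm, outcome(), ews_events([]), demand_cfg()) == []


# -- class balance ----------------------------------------------------------


@pytest.mark.parametrize(
    "pos,neg,text",
    [(2, 30, "1:15"), (0, 10, None), (5, 0, "1:0")],
)
def test_class_balance_rendering(pos, neg, text):
    labels = [1] * pos + [0] * neg
    samples = pd.DataFrame({"label": labels})
    bal = cf.class_balance(samples)
    assert (bal.positives, bal.negatives) == (pos, neg)
    assert bal.ratio_text == text


def test_unknown_structure_rejected():
    with pytest.raises(ConfigurationError):
        cf.FramingConfig(structure="at_event")


def test_cohort_ratio_ordering_across_structures(synth200, synth200_labels):
    """Negatives-per-positive strictly increases fixed < demand < dynamic < sliding."""
    labels, provider = synth200_labels
    cohort = synth200.cohort
    ratios = {}
    for s in cf.STRUCTURES:
        cfg = cf.FramingConfig(structure=s, seed=3, **CFG)
        samples = cf.frame_cohort(cohort, labels, cfg, sofa_provider=provider)
        bal = cf.class_balance(samples)
        ratios[s] = bal.ratio
    assert (
        ratios["fixed_time_to_onset"]
        < ratios["on_clinical_demand"]
        < ratios["sliding_window_dynamic"]
        < ratios["sliding_window"]
    )
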