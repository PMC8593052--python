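import numpy as np
import pandas as pd
import pytest

import clinframe as cf


@pytest.fixture(scope="session")
def synth200():
    """Session-wide small synthetic cohort with planted sepsis episodes."""
    return cf.generate_cohort(cf.GeneratorConfig(n_admissions=200, seed=11))


@pytest.fixture(scope="session")
def synth200_labels(synth200):
    provider = cf.sofa_provider_from_table(synth200.cohort, synth200.sofa)
    return cf.label_cohort(synth200.cohort, cf.Sepsis3Config(), provider), provider


@pytest.fixture()
def tiny_cohort():
    """Two admissions, hand-written measurements and events."""
    admissions = pd.DataFrame(
        {
            "admission_id": ["A1", "A2"],
            "patient_id": ["P1", "P2"],
            "admit_time": [0.0, 100.0],
            "discharge_time": [60.0, 148.0],
        }
    )
    measurements = pd.DataFrame(
        {
            "admission_id": ["A1"] * 6 + ["A2"] * 4,
            "time": [1.0, 2.0, 10.0, 20.5, 30.0, 59.0, 101.0, 110.0, 120.0, 147.0],
            "parameter": [
                "Pulse",
                "Pulse",
                "B-Platelets",
                "Temperature",
                "P-Creatinine",
                "Pulse",
                "Pulse",
                "SpO2",
                "B-Platelets",
                "Pulse",
            ],
            "value": [80.0, 90.0, 250.0, 36.8, 85.0, 77.0, 70.0, 97.0, 260.0, 72.0],
        }
    )
    events = pd.DataFrame(
        {
            "admission_id": ["A1", "A1", "A2"],
            "time": [5.0, 12.0, 115.0],
            "kind": ["culture_sample", "antibiotic_administration", "ews_assessment"],
        }
    )
    return cf.Cohort(admissions, measurements, events)


def make_admission(admission_id="A1", admit=0.0, discharge=48.0, patient_id="P1"):
    return cf.Admission(admission_id, patient_id, admit, discharge)
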