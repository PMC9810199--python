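import pytest

from omopflow.synthetic import (SyntheticConfig, generate_er_visits,
                                generate_inpatient_cohort,
                                generate_outpatient_visits,
                                generate_patient_journeys)


@pytest.fixture(scope="session")
def inpatient_small():
    """40-patient inpatient cohort with the default planted pathway."""
    cfg = SyntheticConfig(seed=11, n_patients=40)
    dataset, truth = generate_inpatient_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def outpatient_dataset():
    cfg = SyntheticConfig(seed=5, n_patients=60)
    dataset, truth = generate_outpatient_visits(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def er_dataset():
    cfg = SyntheticConfig(seed=7, n_patients=60)
    dataset, truth = generate_er_visits(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def journey_dataset():
    cfg = SyntheticConfig(seed=3, n_patients=80)
    dataset, truth = generate_patient_journeys(cfg)
    return cfg, dataset, truth
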