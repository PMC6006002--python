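import pytest

from prrtdose import (CohortConfig, generate_cohort,
                      synthetic_dose_factor_table)


@pytest.fixture(scope="session")
def table():
    return synthetic_dose_factor_table("male")


@pytest.fixture(scope="session")
def table_female():
    return synthetic_dose_factor_table("female")


@pytest.fixture(scope="session")
def noiseless_cohort():
    config = CohortConfig(n_patients=4, noise_sd=0.0, blood_noise_sd=0.0,
                          perturbation_sd=0.0, seed=42)
    return generate_cohort(config)
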