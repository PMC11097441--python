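import numpy as np
import pytest

from emrbert.comorbidity import TriggerSpec
from emrbert.synthetic import (CohortConfig, default_noise_codes,
                               default_trigger_spec, generate_cohort,
                               worked_example)


@pytest.fixture(scope="session")
def fig_record():
    """The four-visit worked-example record."""
    return worked_example()


@pytest.fixture(scope="session")
def noise_codes():
    return tuple(default_noise_codes())


@pytest.fixture(scope="session")
def trigger_spec() -> TriggerSpec:
    return default_trigger_spec()


@pytest.fixture(scope="session")
def small_cohort(noise_codes):
    """A deterministic 60-patient cohort shared across tests."""
    cfg = CohortConfig(n_patients=60)
    return generate_cohort(cfg, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
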