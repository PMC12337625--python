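import numpy as np
import pytest

from iatpsim.cohort_synth import CohortParams, sample_cohort, simulate_cohort
from iatpsim.device_model import DeviceConfig


@pytest.fixture(scope="session")
def nominal_config() -> DeviceConfig:
    return DeviceConfig.nominal()


@pytest.fixture(scope="session")
def sim336():
    """A full-size simulated cohort (336 patients) shared across tests."""
    cohort = sample_cohort(CohortParams(n_patients=336, seed=1))
    return simulate_cohort(cohort)


@pytest.fixture(scope="session")
def adjudicated336(sim336):
    from iatpsim.pipeline import adjudicate_cohort

    return adjudicate_cohort(sim336)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
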