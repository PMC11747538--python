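import numpy as np
import pytest

from sleepcal import CohortConfig, generate_cohort
from sleepcal.metrics import derive_cohort_metrics


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (6 participants, 64 nights)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_paired(default_cohort):
    paired, flags = derive_cohort_metrics(default_cohort)
    assert not flags
    return paired


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
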