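import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bloomline as bl

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted-effect cohort (144 samples, 200 OTUs)."""
    return bl.simulate_cohort(seed=0)


@pytest.fixture(scope="session")
def planted_count_matrix(planted_cohort):
    c = planted_cohort
    return bl.CountMatrix(c.counts, c.spike_counts, c.metadata["weight_g"], c.metadata["spike_uL"])


@pytest.fixture(scope="session")
def planted_spike_equiv(planted_count_matrix):
    return bl.spike_adjusted(planted_count_matrix)


@pytest.fixture(scope="session")
def treated_mask(planted_cohort):
    return (planted_cohort.metadata["treatment"].astype(str) == "ACA").to_numpy()


def small_null_params(n_otus=50, depth=2000):
    return bl.GeneratorParams.null(n_otus=n_otus, sequencing_depth=depth)
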