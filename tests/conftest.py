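import warnings

import numpy as np
import pytest

from timeuse import matching, synthetic as syn

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_study():
    """A small zero-noise-friendly cohort shared by model-level tests."""
    cfg = syn.CohortConfig(
        n_participants=40, days_per_participant=4, seed=21,
        nonwear_mean_min=0, nonwear_sd_min=0,
        person_dispersion=0.06, day_dispersion=0.03,
        academic_missing_prob=0.1, schedule_grid_min=5,
    )
    return syn.generate_study(cfg)


@pytest.fixture(scope="session")
def small_table(small_study):
    return matching.records_from_study(small_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
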