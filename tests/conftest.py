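import warnings

import numpy as np
import pytest

from pronecg import SyntheticCohortConfig, simulate_cohort
from pronecg.errors import RankDeficientWarning


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free cohort shared by read-only tests."""
    cfg = SyntheticCohortConfig(n_subjects=10, total_beats=85, noise_sd=0.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = SyntheticCohortConfig(n_subjects=6, total_beats=50, noise_sd=0.05, seed=12)
    return simulate_cohort(cfg)


@pytest.fixture()
def suppress_rank_warning():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RankDeficientWarning)
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
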