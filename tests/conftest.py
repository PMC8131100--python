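import numpy as np
import pytest

from gemcm.synthetic import SyntheticCohortConfig, gen_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort for structural / IO / CLI tests."""
    cfg = SyntheticCohortConfig(n_subjects=3, n_rois=12, n_genes=8,
                                n_timepoints=4, n_active_params=6, seed=123)
    return gen_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero observation noise: the inverse problem is exactly linear."""
    cfg = SyntheticCohortConfig(n_subjects=2, n_rois=15, n_genes=10,
                                n_timepoints=5, n_active_params=8,
                                obs_noise_sd=0.0, seed=7)
    return gen_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
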