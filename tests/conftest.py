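import numpy as np
import pytest

import painpi as pp


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject, 4-cluster cohort used by several suites."""
    cfg = pp.CohortConfig(n_subjects=12, obs_per_subject_level=6,
                          missing_rate=0.0, seed=42)
    return pp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def oracle_data():
    """Known-quantile Gaussian regression (train, test), alpha = 0.1."""
    train = pp.generate_known_quantile_regression(1000, seed=11, alpha=0.1)
    test = pp.generate_known_quantile_regression(1000, seed=12, alpha=0.1)
    return train, test


@pytest.fixture
def toy_batch():
    """Three-interval batch with hand-countable coverage (2 of 3)."""
    return pp.IntervalBatch(lower=[0.0, 0.0, 2.0],
                            upper=[2.0, 1.0, 4.0],
                            target=[1.0, 2.0, 3.0])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
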