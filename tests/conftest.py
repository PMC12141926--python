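import numpy as np
import pytest

import parenclitic as pc


@pytest.fixture(scope="session")
def default_cfg():
    return pc.default_config(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 162-patient synthetic cohort with the documented defaults."""
    cfg = pc.default_config(seed=42)
    cohort, truth = pc.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def large_cohort():
    """A 1000-patient cohort for recovery checks (same defaults otherwise)."""
    cfg = pc.default_config(seed=7)
    cfg.n_patients = 1000
    cohort, truth = pc.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
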