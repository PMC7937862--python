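import numpy as np
import pytest

from resilnet.cohort import CohortConfig, simulate_cohort
from resilnet.inference import preprocess


@pytest.fixture(scope="session")
def small_study():
    """A 60-subject, 4-visit synthetic cohort with published-preset betas."""
    cfg = CohortConfig(n_subjects=60, visit_months=(0, 12, 24, 36), seed=7)
    cohort, visits = simulate_cohort(cfg, seed=7)
    data, info = preprocess(cohort, visits)
    return cohort, visits, data, info


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
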