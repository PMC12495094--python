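import numpy as np
import pytest

import fcprog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort shared by read-only tests."""
    cfg = fcprog.CohortConfig(
        n_subjects=16, n_regions=10, n_timepoints=40,
        effect_r2=0.5, n_causal_edges=3, attrition_fraction=0.25, seed=11,
    )
    return fcprog.generate_cohort(cfg)
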