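import numpy as np
import pytest

from funcontrol import SyntheticConfig, generate_switching_lds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-subject switching cohort reused by several tests."""
    cfg = SyntheticConfig(
        n_subjects=2,
        n_regions=12,
        n_timepoints=420,
        n_modules=3,
        n_epochs=3,
        seed=7,
    )
    return generate_switching_lds(cfg)
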