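import numpy as np
import pytest

from fct.synthdata import CohortConfig, build_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small but complete synthetic cohort shared across tests."""
    cfg = CohortConfig(
        n_subjects=36,
        n_runs=2,
        n_frames=400,
        n_task=6,
        n_self=6,
        n_unclassified=2,
        seed=7,
    )
    return build_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
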