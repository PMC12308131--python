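from __future__ import annotations

import pytest

from lpfcourse import pipeline, simulate
from lpfcourse.config import CohortConfig


@pytest.fixture(scope="session")
def small_cohort():
    """One small default-condition cohort shared across tests."""
    config = CohortConfig(n_patients=12, seed=1)
    clinical, brain, cord, truth = simulate.generate_cohort(config)
    return config, clinical, brain, cord, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, clinical, brain, cord, _ = small_cohort
    return pipeline.build_features(clinical, brain, cord)
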