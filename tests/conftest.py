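import numpy as np
import pytest

from trustfuse import pipeline
from trustfuse.synthetic import ArtifactConfig, CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_clean_cohort():
    """4 participants x 3 scenarios with every nuisance source disabled."""
    return simulate_cohort(4, CohortConfig.clean(), seed=11)


@pytest.fixture(scope="session")
def small_default_cohort():
    """4 participants x 3 scenarios under the default contaminated conditions."""
    return simulate_cohort(4, CohortConfig(), seed=12)


@pytest.fixture(scope="session")
def fused_table(small_default_cohort):
    table = pipeline.score_cohort(small_default_cohort)
    table, model, info = pipeline.fuse_scores(table, run_loocv=False)
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
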