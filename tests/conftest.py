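import numpy as np
import pytest

from plasmapanel import generate_cohort, study_like_config


@pytest.fixture(scope="session")
def set1_cohort():
    """Study-shaped panel-1 cohort: 7 markers, 35 cases + 38 controls."""
    return generate_cohort(study_like_config(1, seed=11))


@pytest.fixture(scope="session")
def set2_cohort():
    """Study-shaped panel-2 cohort: 6 markers, 29 cases + 16 controls."""
    return generate_cohort(study_like_config(2, seed=11))


@pytest.fixture(scope="session")
def set2_cases(set2_cohort):
    """Case subjects of the panel-2 cohort (the ones with SSP scores)."""
    return set2_cohort.select(subjects=np.isfinite(set2_cohort.severity_score))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
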