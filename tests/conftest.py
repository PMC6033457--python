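import numpy as np
import pandas as pd
import pytest

from adchist.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default synthetic cohort (6 deceased vs 14 survivors), seed 1."""
    return generate_cohort(CohortConfig(seed=1))
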