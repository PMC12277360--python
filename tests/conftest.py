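import numpy as np
import pandas as pd
import pytest

from kscope.microbiome import FeatureTable
from kscope.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort300():
    """Default stated-world cohort, shared across clustering tests."""
    return simulate_cohort(CohortConfig(n_subjects=300, seed=1))


@pytest.fixture(scope="session")
def cohort120():
    return simulate_cohort(CohortConfig(n_subjects=120, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """Tiny hand-checkable genus table."""
    return FeatureTable(
        pd.DataFrame(
            [[6, 2, 0], [2, 6, 0], [0, 0, 8], [5, 1, 2]],
            index=["s1", "s2", "s3", "s4"],
            columns=["GenA", "GenB", "GenC"],
        )
    )
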