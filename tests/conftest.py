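import numpy as np
import pytest

from ssmrs import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """One default two-group cohort (51 subjects), shared across tests."""
    spec = syn.CohortSpec(seed=42)
    return syn.simulate_cohort(spec)
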