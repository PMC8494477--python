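import numpy as np
import pytest
from hypothesis import settings

from prevalence import BetaPrior, PrevalencePosterior, TestResultCounts

# derandomised so the suite is reproducible run to run
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def worked_counts() -> TestResultCounts:
    """32 of 50 units significant at alpha = 0.05."""
    return TestResultCounts(32, 50, 0.05)


@pytest.fixture
def worked_posterior(worked_counts) -> PrevalencePosterior:
    return PrevalencePosterior(worked_counts, BetaPrior())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
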