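import warnings

import numpy as np
import pytest

from confidence_lab import experiments as E

warnings.filterwarnings("ignore", message="evaluator is not increasing")


@pytest.fixture(scope="session")
def two_choice_cohort():
    """Two supervised two-choice networks trained under the standard
    variable-contrast/variable-noise regime (shared across tests)."""
    return E.train_two_choice_cohort(2, n_per_class=300, epochs=3, seed=0)


@pytest.fixture(scope="session")
def rl_cohort():
    """Two actor-critic networks trained on the Gabor opt-out task at
    reduced iteration count (shared across RL tests)."""
    return E.train_rl_cohort(2, iterations=1500, seed=3)


@pytest.fixture(scope="session")
def synth_pool():
    return E.synth_test_pool(n_per_class=250, separation=3.0, seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
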