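import numpy as np
import pytest

from discordancy import ALL_TESTS, build_cv_table


@pytest.fixture(scope="session")
def cv_table_small():
    """Modest-replication critical values for unit tests (all tests, n=5, 10)."""
    return build_cv_table(ALL_TESTS, [5, 10], [0.95, 0.99], reps=100_000, base_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(8675309)
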