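import numpy as np
import pytest

from shelfspace.config import default_config


@pytest.fixture(scope="session")
def small_config():
    """20-gene default-style config; session-scoped, treat as read-only."""
    return default_config(n_genes=20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
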