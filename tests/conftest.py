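import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cardiosync.simulate import simulate_fixture_small


@pytest.fixture(scope="session")
def small_session():
    """Deterministic 2-quartet fixture session (manifest, tachograms, ratings)."""
    return simulate_fixture_small(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
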