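import random
import sys
from pathlib import Path

import numpy as np
import pytest

# make the brute-force oracle helpers importable as `oracles`
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    """Seeded stdlib RNG for structural randomization in tests."""
    return random.Random(42)


@pytest.fixture
def nprng():
    """Seeded NumPy generator for sequence simulation in tests."""
    return np.random.default_rng(42)
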