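import numpy as np
import pytest

from follireg3d import generate


@pytest.fixture(scope="session")
def sim():
    """Default synthetic dataset, shared across the suite (seed-fixed)."""
    return generate(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
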