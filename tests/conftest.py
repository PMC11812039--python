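import numpy as np
import pytest
from hypothesis import settings

import arborscale as arb

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pareto_sample():
    """Sharp power-law sample: alpha=2, xm=1, n=10^4."""
    return arb.sample_diameters(2.0, 1.0, 10_000, seed=11)


@pytest.fixture(scope="session")
def random_tree():
    """A mid-sized asymmetric tree (alpha=2, defaults)."""
    return arb.generate_tree(alpha=2.0, seed=5)


@pytest.fixture(scope="session")
def symmetric_tree():
    """Perfectly symmetric alpha=2 tree with terminals at generation 7."""
    return arb.generate_tree(alpha=2.0, asymmetry_low=1.0, asymmetry_high=1.0,
                             stop_ratio=0.09, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
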