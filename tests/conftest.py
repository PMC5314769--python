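import numpy as np
import pytest

from resdyn import synthetic as syn


@pytest.fixture
def toy_complex():
    """Deterministic toy protein-DNA complex, no planted features."""
    st, truth = syn.make_toy_complex(seed=1)
    return st, truth


@pytest.fixture
def site_complex():
    """Toy complex with a catalytic site (Mg/OE1/OE2/P) and a water pool."""
    st, truth = syn.make_toy_complex(seed=1, include_site=True, n_waters=10)
    return st, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_contacts(coords_a, coords_b, cutoff):
    """O(n^2) oracle: unordered pairs (a, b) with distance <= cutoff."""
    pairs = []
    for i, p in enumerate(coords_a):
        for j, q in enumerate(coords_b):
            if np.linalg.norm(p - q) <= cutoff:
                pairs.append((i, j))
    return pairs
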