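import numpy as np
import pytest

from motifload import ReferenceGenome, builtin_registry, make_genome


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def small_genome():
    """100 kb uniform-composition genome used across unit tests."""
    return make_genome(length=100_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_window(rng, min_len=5, max_len=41, alphabet="ACGTN", n_prob=0.05):
    """A random sequence for property tests; N appears with small probability."""
    length = int(rng.integers(min_len, max_len + 1))
    probs = np.full(4, (1 - n_prob) / 4)
    probs = np.append(probs, n_prob)
    return "".join(rng.choice(list(alphabet), size=length, p=probs))
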