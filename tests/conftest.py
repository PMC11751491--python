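import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    from dietmap import simulate_genome

    return simulate_genome(100_000, seed=4242, name="chr_t")


@pytest.fixture(scope="session")
def small_index(small_genome):
    from dietmap import build_index, parse_pattern

    return build_index([small_genome], parse_pattern("10"), 19, 16)
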