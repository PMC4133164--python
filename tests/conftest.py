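import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def make_dna():
    def _make(n, seed=0):
        r = np.random.default_rng(seed)
        return "".join(r.choice(list("ACGT"), size=n))

    return _make
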