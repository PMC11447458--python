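import numpy as np
import pytest

from rdnaunit import coturnix_spec, generate_unit


@pytest.fixture(scope="session")
def truth():
    """The default synthetic quail-like unit (seed 1) with planted ground truth."""
    return generate_unit(coturnix_spec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length, gc=0.5):
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("GCAT"), size=length, p=p))
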