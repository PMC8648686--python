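import numpy as np
import pytest

from canningsim.offspring_laws import make_ylaw


@pytest.fixture
def rng():
    """Default deterministic generator for tests."""
    return np.random.default_rng(20240901)


@pytest.fixture
def gamma2():
    """The workhorse law: gamma with shape 2, normalized to mean 1."""
    return make_ylaw("gamma", (2.0,))


@pytest.fixture
def det1():
    return make_ylaw("deterministic", (1.0,))
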