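import numpy as np
import pytest
from pathimpute.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny():
    """30 cells x 20 genes, two layers; unit-test scale."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def layered():
    """500 cells x 200 genes with both spatial and cell-type signal."""
    return make_fixture("layered")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
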