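import numpy as np
import pytest

from expevo import BMContext
from expevo.synthetic import default_tree


@pytest.fixture(scope="session")
def tree9():
    return default_tree()


@pytest.fixture(scope="session")
def ctx9(tree9):
    return BMContext.from_tree(tree9)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
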