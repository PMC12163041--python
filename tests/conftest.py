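import numpy as np
import pytest

from topobrain.rips import warm_up


@pytest.fixture(scope="session", autouse=True)
def _compile_kernels():
    """Compile the numba persistence kernels once per test session."""
    warm_up()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
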