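import numpy as np
import pytest

from spmekfw.datasets import load_test, load_training


@pytest.fixture(scope="session")
def training():
    return load_training()


@pytest.fixture(scope="session")
def test_set():
    return load_test()


@pytest.fixture(scope="session")
def log_kfw(training):
    return np.log10(training["kfw"].to_numpy(dtype=float))
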