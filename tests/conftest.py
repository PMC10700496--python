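import numpy as np
import pytest

from bayes2pl import GeneratingCondition, ResponseMatrix, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_dataset():
    """One typical-variance replication, small enough for fast fits."""
    return generate_dataset(GeneratingCondition(60, 12, (0.25, 0.90), 0.3, seed=11))


@pytest.fixture(scope="session")
def small_y(small_dataset):
    return small_dataset.responses


@pytest.fixture()
def toy_y():
    """2 x 2 complete toy response matrix."""
    return ResponseMatrix(np.array([[1, 0], [0, 1]]))
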