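import numpy as np
import pytest

from pgms import synthetic as syn


@pytest.fixture(scope="session")
def dataset1():
    data, truth = syn.generate_with_truth(syn.dataset1_spec(), syn.dataset1_config(seed=1))
    return data, truth


@pytest.fixture(scope="session")
def dataset2():
    data, truth = syn.generate_with_truth(syn.dataset2_spec(), syn.dataset2_config(seed=1))
    return data, truth


@pytest.fixture()
def rng():
    return np.random.RandomState(12345)
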