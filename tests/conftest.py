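import copy

import numpy as np
import pytest

from schizodes import builtin_config_path, load_parameter_set


@pytest.fixture(scope="session")
def illustrative():
    return load_parameter_set(builtin_config_path("illustrative_uk"))


@pytest.fixture(scope="session")
def minimal():
    return load_parameter_set(builtin_config_path("minimal_test"))


@pytest.fixture()
def minimal_copy(minimal):
    return copy.deepcopy(minimal)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def make_rng(seed: int = 12345) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))
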