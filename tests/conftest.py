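import numpy as np
import pytest

from pepgood import GeneratorConfig, generate_dataset
from pepgood.monomers import CANONICAL_LETTERS


def random_sequence(rng, lo=4, hi=12):
    length = int(rng.integers(lo, hi + 1))
    return "".join(CANONICAL_LETTERS[i]
                   for i in rng.integers(len(CANONICAL_LETTERS), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(GeneratorConfig(n=60, seed=11))


@pytest.fixture(scope="session")
def regression_dataset():
    return generate_dataset(GeneratorConfig(n=60, task="regression", seed=12))
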