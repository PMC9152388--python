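import numpy as np
import pytest

from cnerkit.tagging import DEFAULT_SCHEMA
from cnerkit.synthetic import GeneratorSpec, generate_corpus


@pytest.fixture(scope="session")
def schema():
    return DEFAULT_SCHEMA


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic 50-sentence synthetic corpus."""
    return generate_corpus(GeneratorSpec(seed=7), 50)
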