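import numpy as np
import pytest

from vteal import GeneratorConfig, generate_corpus, separable_config


@pytest.fixture(scope="session")
def default_corpus():
    """The full 5,839-report study-profile corpus."""
    return generate_corpus(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_corpus():
    """Balanced, noise-free 210-report corpus for fast unit tests."""
    return generate_corpus(separable_config(210, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
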