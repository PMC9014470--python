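import pytest

from splitner.corpus_io import LabelScheme
from splitner.synthetic_data import GeneratorConfig, generate_corpus


@pytest.fixture
def scheme():
    return LabelScheme()


@pytest.fixture(scope="session")
def default_data():
    """One moderately sized generated corpus pair, shared across tests."""
    return generate_corpus(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_data():
    return generate_corpus(
        GeneratorConfig(
            seed=5,
            n_train_docs=10,
            n_test_docs=8,
            n_concepts=10,
            synonyms_per_concept=2,
        )
    )
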