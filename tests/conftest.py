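import pytest

from cause_al import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """~1,200-sentence synthetic corpus shared by read-only tests."""
    return generate_corpus(GeneratorConfig(n_documents=60, seed=42))


@pytest.fixture(scope="session")
def tiny_corpus():
    """~200-sentence corpus for tests that train models."""
    return generate_corpus(GeneratorConfig(n_documents=12, n_topics=4, seed=7))
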