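import pytest

from pamt import (
    Corpus,
    GeneratorConfig,
    Transcript,
    expert_keyword_list,
    generate_certainty_votes,
    generate_corpus,
)


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def study_corpus(default_cfg):
    """Study-sized synthetic corpus: 114 cases, 42 positive, with votes."""
    corpus, truth = generate_corpus(default_cfg)
    corpus = generate_certainty_votes(default_cfg, corpus)
    return corpus, truth


@pytest.fixture(scope="session")
def expert_keywords(default_cfg):
    return set(expert_keyword_list(default_cfg))


@pytest.fixture
def toy_corpus() -> Corpus:
    """Three tiny documents with hand-computable term statistics."""
    return Corpus(
        [
            Transcript(id="d1", tokens=["a", "a", "b"], label="pamt"),
            Transcript(id="d2", tokens=["b", "c"], label="non_pamt"),
            Transcript(id="d3", tokens=["c", "c", "c"], label="non_pamt"),
        ]
    )
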