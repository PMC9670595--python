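import pytest

import medtypo as m
from medtypo.fixtures import tokenized


@pytest.fixture(scope="session")
def prose_resources():
    """Prose training corpus with dictionary, delete index, and n-gram LM."""
    train_lines = m.generate_prose_corpus(2000, seed=1)
    dictionary = m.build_dictionary(train_lines, min_count=20)
    index = m.build_index(dictionary, max_distance=2)
    lm = m.train_ngram_backend(tokenized(train_lines))
    return {
        "train_lines": train_lines,
        "dictionary": dictionary,
        "index": index,
        "lm": lm,
    }


@pytest.fixture(scope="session")
def spr_resources():
    """SPR fixture corpus (tagger data) plus corrector resources built from a
    larger independent SPR sample."""
    tagged, lines = m.generate_spr_corpus(m.FixtureSpec(n_sentences=200, seed=7))
    big_tagged, big_lines = m.generate_spr_corpus(
        m.FixtureSpec(n_sentences=1000, seed=11)
    )
    dictionary = m.build_dictionary(big_lines, min_count=20)
    index = m.build_index(dictionary, max_distance=2)
    lm = m.train_ngram_backend(tokenized(big_lines))
    return {
        "tagged": tagged,
        "lines": lines,
        "dictionary": dictionary,
        "index": index,
        "lm": lm,
    }
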