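import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import medtypo as m
from medtypo.candidates import damerau_levenshtein
from medtypo.error_model import (
    CapacityError,
    ErrorType,
    SplitPair,
    _LETTERS,
    apply_error,
    corrupt_corpus,
    eligible_splits,
    enumerate_splits,
)
from medtypo.lexicon import tokenize

words = st.text(alphabet=st.sampled_from("abcdefgh"), min_size=1, max_size=12)


class _FixedLetter:
    """Generator stand-in that always draws a chosen letter."""

    def __init__(self, letter):
        self.index = _LETTERS.index(letter)

    def integers(self, n):
        assert n == len(_LETTERS)
        return self.index


def test_enumerate_splits_random():
    splits = enumerate_splits("random")
    assert len(splits) == 7
    assert (splits[0].left, splits[0].right) == ("", "random")
    assert (splits[-1].left, splits[-1].right) == ("random", "")


def test_enumerate_splits_single_letter_and_empty():
    assert [(s.left, s.right) for s in enumerate_splits("a")] == [("", "a"), ("a", "")]
    with pytest.raises(ValueError):
        enumerate_splits("")


@given(words)
@settings(max_examples=100, deadline=None)
def test_split_counts(word):
    assert len(enumerate_splits(word)) == len(word) + 1
    elig = eligible_splits(word)
    assert len(elig) == len(word) - 1
    for s in elig:
        assert s.left and s.right and s.left + s.right == word


def test_eligible_splits_examples():
    assert len(eligible_splits("random")) == 5
    assert [(s.left, s.right) for s in eligible_splits("ab")] == [("a", "b")]
    assert eligible_splits("a") == []


@pytest.mark.parametrize(
    "etype, letter, expected",
    [
        (ErrorType.DELETE, None, "randm"),
        (ErrorType.TRANSPOSE, None, "randmo"),
        (ErrorType.INSERT, "c", "randcom"),
        (ErrorType.REPLACE, "c", "randcm"),
    ],
)
def test_corruption_operators_on_rand_om(etype, letter, expected):
    split = SplitPair("rand", "om")
    rng = _FixedLetter(letter) if letter else np.random.default_rng(0)
    assert apply_error(split, etype, rng) == expected


def test_transpose_rejects_short_or_noop_right():
    with pytest.raises(ValueError):
        apply_error(SplitPair("rando", "m"), ErrorType.TRANSPOSE, np.random.default_rng(0))
    with pytest.raises(ValueError):
        apply_error(SplitPair("b", "oo"), ErrorType.TRANSPOSE, np.random.default_rng(0))


def test_replace_never_reproduces_original():
    rng = np.random.default_rng(0)
    for _ in range(200):
        assert apply_error(SplitPair("a", "b"), ErrorType.REPLACE, rng) != "ab"


def test_delete_then_insert_round_trip():
    # deleting a letter and re-inserting it at the same split restores the word
    split = SplitPair("rand", "om")
    deleted = apply_error(split, ErrorType.DELETE, np.random.default_rng(0))
    assert deleted == "randm"
    restored = SplitPair("rand", deleted[4:])
    letter = "o"
    assert restored.left + letter + restored.right == "random"


@pytest.fixture()
def corpus():
    lines = [
        "the right lung was examined",
        "a long segment of tissue was submitted",
        "the chest wall is intact and free of tumor",
        "no residual carcinoma is identified in the specimen",
    ] * 5
    return [tokenize(line) for line in lines]


def test_corrupt_corpus_balancing_and_distance(corpus):
    corrupted, records = corrupt_corpus(corpus, total_errors=16,
                                        rng=np.random.default_rng(3))
    assert len(records) == 16
    counts = {t: 0 for t in ErrorType}
    for r in records:
        counts[r.error_type] += 1
        assert r.corrupted != r.original
        assert damerau_levenshtein(r.original, r.corrupted) == 1
        assert corrupted[r.sentence_index].tokens[r.token_index] == r.corrupted
        assert corpus[r.sentence_index].tokens[r.token_index] == r.original
    assert all(c == 4 for c in counts.values())  # 16 divisible by 4


def test_corrupt_corpus_total_four_gives_one_of_each(corpus):
    _, records = corrupt_corpus(corpus, total_errors=4, rng=np.random.default_rng(1))
    assert sorted(r.error_type.value for r in records) == sorted(t.value for t in ErrorType)


def test_corrupt_corpus_zero_and_determinism(corpus):
    out, records = corrupt_corpus(corpus, total_errors=0, rng=np.random.default_rng(0))
    assert records == [] and [s.tokens for s in out] == [s.tokens for s in corpus]
    a = corrupt_corpus(corpus, total_errors=16, rng=np.random.default_rng(9))
    b = corrupt_corpus(corpus, total_errors=16, rng=np.random.default_rng(9))
    assert a[1] == b[1]
    assert [s.tokens for s in a[0]] == [s.tokens for s in b[0]]


def test_corrupt_corpus_balance_within_one(corpus):
    _, records = corrupt_corpus(corpus, total_errors=10, rng=np.random.default_rng(5))
    counts = [sum(r.error_type is t for r in records) for t in ErrorType]
    assert max(counts) - min(counts) <= 1


def test_corrupt_corpus_rate_interface(corpus):
    eligible = sum(
        1 for s in corpus for t in s.tokens if len(t) >= 2 and t.isalpha()
    )
    _, records = corrupt_corpus(corpus, rate=0.1, rng=np.random.default_rng(2))
    assert len(records) == round(0.1 * eligible)
    with pytest.raises(ValueError):
        corrupt_corpus(corpus, total_errors=1, rate=0.1)
    with pytest.raises(ValueError):
        corrupt_corpus(corpus)


def test_corrupt_corpus_capacity_error():
    tiny = [tokenize("ab cd")]
    with pytest.raises(CapacityError):
        corrupt_corpus(tiny, total_errors=5, rng=np.random.default_rng(0))


def test_records_tsv_round_trip(tmp_path, corpus):
    from medtypo.error_model import load_records, save_records

    _, records = corrupt_corpus(corpus, total_errors=8, rng=np.random.default_rng(4))
    path = tmp_path / "records.tsv"
    save_records(records, path)
    assert load_records(path) == records


@given(words.filter(lambda w: len(w) >= 2), st.integers(0, 2**31 - 1))
@settings(max_examples=100, deadline=None)
def test_single_corruptions_are_distance_one(word, seed):
    """Any operator applied at any eligible split is one OSA edit away."""
    rng = np.random.default_rng(seed)
    sent = [m.tokenize(word)]
    try:
        _, records = corrupt_corpus(sent, total_errors=1, rng=rng)
    except CapacityError:
        return
    (rec,) = records
    assert damerau_levenshtein(rec.original, rec.corrupted) == 1
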