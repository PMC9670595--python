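"""Random typo injection.

A word is split into a (left, right) pair at a random interior point and one
of four single-keystroke corruption operators is applied at the boundary:

* INSERT     — a random ASCII letter is inserted between the two strings
* DELETE     — the first character of the right string is removed
* REPLACE    — a random letter (differing from the original) replaces the
               first character of the right string
* TRANSPOSE  — the first two characters of the right string are swapped

Every injected corruption is therefore exactly one Damerau-Levenshtein edit
away from the original word.  Corpus-level injection balances the four
operator counts to within one, mirroring experiments that report matched
per-type error counts.
"""

from __future__ import annotations

import enum
import string
from dataclasses import dataclass

import numpy as np

from .lexicon import TokenizedSentence, is_word_token

__all__ = [
    "ErrorType",
    "SplitPair",
    "CorruptionRecord",
    "enumerate_splits",
    "eligible_splits",
    "apply_error",
    "corrupt_corpus",
    "CapacityError",
]

_LETTERS = string.ascii_uppercase + string.ascii_lowercase


class ErrorType(enum.Enum):
    INSERT = "insert"
    DELETE = "delete"
    REPLACE = "replace"
    TRANSPOSE = "transpose"


@dataclass(frozen=True)
class SplitPair:
    left: str
    right: str

    @property
    def word(self) -> str:
        return self.left + self.right

    @property
    def point(self) -> int:
        return len(self.left)


@dataclass(frozen=True)
class CorruptionRecord:
    """Provenance of one injected typo."""

    sentence_index: int
    token_index: int
    original: str
    corrupted: str
    error_type: ErrorType
    split_point: int


class CapacityError(ValueError):
    """Raised when a corpus has too few eligible tokens for the request."""


def enumerate_splits(word: str) -> list[SplitPair]:
    """All len(word)+1 left/right splits in left-to-right order."""
    if not word:
        raise ValueError("cannot split the empty word")
    return [SplitPair(word[:i], word[i:]) for i in range(len(word) + 1)]


def eligible_splits(word: str) -> list[SplitPair]:
    """Splits with both sides non-empty (n-1 pairs for a length-n word)."""
    if not word:
        raise ValueError("cannot split the empty word")
    return [SplitPair(word[:i], word[i:]) for i in range(1, len(word))]


def apply_error(
    split: SplitPair,
    error_type: ErrorType,
    rng: np.random.Generator,
) -> str:
    """Apply one corruption operator at the split boundary.

    The result always differs from the source word: REPLACE redraws its random
    letter until it differs from the replaced character, and TRANSPOSE refuses
    no-op swaps (equal adjacent characters) as well as right strings shorter
    than two characters.
    """
    left, right = split.left, split.right
    if not left or not right:
        raise ValueError("both sides of the split must be non-empty")
    if error_type is ErrorType.INSERT:
        letter = _LETTERS[rng.integers(len(_LETTERS))]
        return left + letter + right
    if error_type is ErrorType.DELETE:
        return left + right[1:]
    if error_type is ErrorType.REPLACE:
        letter = _LETTERS[rng.integers(len(_LETTERS))]
        while letter == right[0]:
            letter = _LETTERS[rng.integers(len(_LETTERS))]
        return left + letter + right[1:]
    if error_type is ErrorType.TRANSPOSE:
        if len(right) < 2:
            raise ValueError("transpose needs at least two characters on the right")
        if right[0] == right[1]:
            raise ValueError("transpose of equal adjacent characters is a no-op")
        return left + right[1] + right[0] + right[2:]
    raise TypeError(f"unknown error type: {error_type!r}")


def _transpose_splits(word: str) -> list[SplitPair]:
    return [
        s for s in eligible_splits(word)
        if len(s.right) >= 2 and s.right[0] != s.right[1]
    ]


def _corruptible(token: str) -> bool:
    # Alphabetic, length >= 2: length-1 words admit no eligible split.
    return len(token) >= 2 and is_word_token(token)


def _balanced_types(total: int, rng: np.random.Generator) -> list[ErrorType]:
    """A shuffled list of ``total`` error types with per-type counts differing
    by at most one (equal when total is divisible by four)."""
    order = list(ErrorType)
    base, extra = divmod(total, 4)
    counts = [base] * 4
    for idx in rng.permutation(4)[:extra]:
        counts[idx] += 1
    types = [t for t, c in zip(order, counts) for _ in range(c)]
    perm = rng.permutation(len(types))
    return [types[i] for i in perm]


def corrupt_corpus(
    sentences: list[TokenizedSentence],
    total_errors: int | None = None,
    rate: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[TokenizedSentence], list[CorruptionRecord]]:
    """Corrupt exactly ``total_errors`` tokens (at most one edit per token).

    Either an absolute count or a ``rate`` (fraction of eligible tokens,
    rounded to nearest) may be given.  The four error-type counts are balanced
    to within one; TRANSPOSE is only assigned to tokens that admit a
    transposition producing a genuine change.
    """
    if (total_errors is None) == (rate is None):
        raise ValueError("specify exactly one of total_errors or rate")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    positions = [
        (si, ti)
        for si, sent in enumerate(sentences)
        for ti, tok in enumerate(sent.tokens)
        if _corruptible(tok)
    ]
    if rate is not None:
        if not 0 <= rate < 1:
            raise ValueError("rate must be in [0, 1)")
        total_errors = int(round(rate * len(positions)))
    assert total_errors is not None
    if total_errors < 0:
        raise ValueError("total_errors must be non-negative")
    if total_errors > len(positions):
        raise CapacityError(
            f"requested {total_errors} errors but only {len(positions)} "
            f"eligible tokens (deficit {total_errors - len(positions)})"
        )
    if total_errors == 0:
        return list(sentences), []

    chosen = [positions[i] for i in rng.choice(len(positions), size=total_errors, replace=False)]
    types = _balanced_types(total_errors, rng)

    # TRANSPOSE can only be applied to tokens with a transpose-eligible split;
    # deterministically swap assignments so every quota is met exactly.
    def can_transpose(pos: tuple[int, int]) -> bool:
        si, ti = pos
        return bool(_transpose_splits(sentences[si].tokens[ti]))

    for i in range(total_errors):
        if types[i] is ErrorType.TRANSPOSE and not can_transpose(chosen[i]):
            for j in range(total_errors):
                if types[j] is not ErrorType.TRANSPOSE and can_transpose(chosen[j]):
                    types[i], types[j] = types[j], types[i]
                    break
            else:
                raise CapacityError(
                    "not enough transposable tokens to balance error types"
                )

    new_tokens: dict[int, list[str]] = {}
    records: list[CorruptionRecord] = []
    for (si, ti), etype in zip(chosen, types):
        word = sentences[si].tokens[ti]
        if etype is ErrorType.TRANSPOSE:
            splits = _transpose_splits(word)
        else:
            splits = eligible_splits(word)
        split = splits[rng.integers(len(splits))]
        corrupted = apply_error(split, etype, rng)
        records.append(
            CorruptionRecord(
                sentence_index=si,
                token_index=ti,
                original=word,
                corrupted=corrupted,
                error_type=etype,
                split_point=split.point,
            )
        )
        new_tokens.setdefault(si, list(sentences[si].tokens))[ti] = corrupted

    out: list[TokenizedSentence] = []
    for si, sent in enumerate(sentences):
        if si in new_tokens:
            toks = tuple(new_tokens[si])
            out.append(TokenizedSentence(tokens=toks, raw=" ".join(toks)))
        else:
            out.append(sent)
    records.sort(key=lambda r: (r.sentence_index, r.token_index))
    return out, records


def save_records(records: list[CorruptionRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sentence_index\ttoken_index\toriginal\tcorrupted\terror_type\tsplit_point\n")
        for r in records:
            fh.write(
                f"{r.sentence_index}\t{r.token_index}\t{r.original}\t"
                f"{r.corrupted}\t{r.error_type.value}\t{r.split_point}\n"
            )


def load_records(path) -> list[CorruptionRecord]:
    records: list[CorruptionRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("sentence_index"):
            raise IOError("missing records header")
        for line in fh:
            si, ti, orig, corr, etype, sp = line.rstrip("\n").split("\t")
            records.append(
                CorruptionRecord(int(si), int(ti), orig, corr, ErrorType(etype), int(sp))
            )
    return records
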