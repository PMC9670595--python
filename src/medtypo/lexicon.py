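"""Tokenization and the word-frequency dictionary.

The dictionary defines what counts as a "known" word for correction: every
alphabetic token whose corpus frequency reaches ``min_count`` (default 20;
rarer strings are treated as noise and excluded, so they can never be offered
as corrections).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "TokenizedSentence",
    "WordDictionary",
    "tokenize",
    "is_word_token",
    "build_dictionary",
    "save_dictionary",
    "load_dictionary",
]

# Maximal runs of letters (internal hyphens/apostrophes allowed), numbers with
# an optional decimal part, or a single non-space symbol.
_TOKEN_RE = re.compile(
    r"[^\W\d_]+(?:['’-][^\W\d_]+)*"  # word, possibly hyphen/apostrophe joined
    r"|\d+(?:\.\d+)?"                      # number, optional decimal
    r"|\S",                                # any other single symbol
    re.UNICODE,
)

_WORD_RE = re.compile(r"[^\W\d_]+(?:['’-][^\W\d_]+)*\Z", re.UNICODE)


@dataclass(frozen=True)
class TokenizedSentence:
    """An ordered token list together with the raw line it came from."""

    tokens: tuple[str, ...]
    raw: str

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def text(self) -> str:
        return " ".join(self.tokens)


def tokenize(text: str) -> TokenizedSentence:
    """Split ``text`` into tokens after NFC normalization.

    Words keep internal hyphens and apostrophes, decimal numbers stay whole
    ("2.1"), and every other symbol (including the multiplication sign used in
    tumor-size strings) becomes its own token.
    """
    norm = unicodedata.normalize("NFC", text)
    return TokenizedSentence(tokens=tuple(_TOKEN_RE.findall(norm)), raw=text)


def is_word_token(token: str) -> bool:
    """True when the token is purely alphabetic (dictionary-eligible shape)."""
    return bool(_WORD_RE.match(token))


@dataclass
class WordDictionary:
    """word -> corpus frequency map with a minimum-count threshold.

    Lookups of absent words return 0; ``case_policy`` is either ``"preserve"``
    or ``"fold_lower"`` (the default — keys are stored lower-cased and queries
    folded before lookup).
    """

    entries: dict[str, int] = field(default_factory=dict)
    min_count: int = 20
    case_policy: str = "fold_lower"

    def __post_init__(self) -> None:
        if self.case_policy not in ("preserve", "fold_lower"):
            raise ValueError(f"unknown case_policy: {self.case_policy!r}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    def _key(self, word: str) -> str:
        return word.lower() if self.case_policy == "fold_lower" else word

    def frequency(self, word: str) -> int:
        return self.entries.get(self._key(word), 0)

    def __contains__(self, word: str) -> bool:
        return self._key(word) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def words(self) -> Iterable[str]:
        return self.entries.keys()


def _eligible(token: str) -> bool:
    # Dictionary eligibility: alphabetic, length >= 2 (single letters and
    # numbers generate pathological candidate sets).
    return len(token) >= 2 and is_word_token(token)


def build_dictionary(
    corpus: Iterable[str],
    min_count: int = 20,
    case_policy: str = "fold_lower",
) -> WordDictionary:
    """Count alphabetic tokens over ``corpus`` lines and keep those with
    frequency >= ``min_count``.

    A word seen exactly ``min_count`` times is retained — only strictly rarer
    words are excluded.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    fold = case_policy == "fold_lower"
    for lineno, line in enumerate(corpus, start=1):
        try:
            sent = tokenize(line)
        except UnicodeError as exc:  # pragma: no cover - exotic streams
            raise IOError(f"cannot decode corpus line {lineno}: {exc}") from exc
        for tok in sent.tokens:
            if not _eligible(tok):
                continue
            key = tok.lower() if fold else tok
            counts[key] = counts.get(key, 0) + 1
    entries = {w: c for w, c in counts.items() if c >= min_count}
    return WordDictionary(entries=entries, min_count=min_count, case_policy=case_policy)


def save_dictionary(dictionary: WordDictionary, path: str | Path | TextIO) -> None:
    """Write a two-column TSV ``word<TAB>count``, descending count then
    lexicographic — deterministic for a given dictionary."""
    rows = sorted(dictionary.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    if hasattr(path, "write"):
        for word, count in rows:
            path.write(f"{word}\t{count}\n")
        return
    with open(path, "w", encoding="utf-8") as fh:
        for word, count in rows:
            fh.write(f"{word}\t{count}\n")


def load_dictionary(
    path: str | Path,
    min_count: int = 20,
    case_policy: str = "fold_lower",
) -> WordDictionary:
    entries: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                word, count_s = line.split("\t")
                count = int(count_s)
            except ValueError as exc:
                raise IOError(f"malformed dictionary line {lineno}: {line!r}") from exc
            if count >= min_count:
                entries[word] = count
    return WordDictionary(entries=entries, min_count=min_count, case_policy=case_policy)
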