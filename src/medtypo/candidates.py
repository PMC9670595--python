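"""Delete-neighborhood candidate generation.

Approximate dictionary lookup in the SymSpell style: every dictionary word is
indexed under each string reachable by deleting up to ``max_distance``
characters.  A query is answered by intersecting its own delete variants with
the index and verifying each surviving word with the restricted
Damerau-Levenshtein distance (optimal string alignment — insertions,
deletions, substitutions and adjacent transpositions each cost one).  The
delete trick overgenerates, so exact verification is mandatory; it never
undergenerates because two strings within OSA distance d always share a
common d-deletion descendant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexicon import WordDictionary

__all__ = [
    "Candidate",
    "DeleteIndex",
    "delete_variants",
    "damerau_levenshtein",
    "build_index",
    "generate_candidates",
]


@dataclass(frozen=True)
class Candidate:
    """A dictionary word within edit distance of the query."""

    term: str
    distance: int
    count: int


def delete_variants(word: str, d: int) -> set[str]:
    """All strings obtainable by deleting up to ``d`` characters (the word
    itself included)."""
    if d < 0:
        raise ValueError("d must be >= 0")
    frontier = {word}
    out = {word}
    for _ in range(min(d, len(word))):
        frontier = {
            w[:i] + w[i + 1:]
            for w in frontier
            for i in range(len(w))
        } - out
        out |= frontier
    return out


def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


@dataclass
class DeleteIndex:
    """Precomputed delete neighborhoods of every dictionary word."""

    dictionary: WordDictionary
    max_distance: int = 2
    variant_map: dict[str, set[str]] = field(default_factory=dict, repr=False)


def build_index(dictionary: WordDictionary, max_distance: int = 2) -> DeleteIndex:
    if max_distance not in (1, 2):
        raise ValueError("max_distance must be 1 or 2")
    variant_map: dict[str, set[str]] = {}
    for word in dictionary.words():
        for variant in delete_variants(word, max_distance):
            variant_map.setdefault(variant, set()).add(word)
    return DeleteIndex(dictionary=dictionary, max_distance=max_distance, variant_map=variant_map)


def generate_candidates(query: str, index: DeleteIndex) -> list[Candidate]:
    """Dictionary words within ``max_distance`` OSA edits of ``query``,
    sorted by (distance asc, count desc, term).

    The query is folded to the dictionary's case policy; returned terms keep
    dictionary form.
    """
    if not query:
        raise ValueError("query must be non-empty")
    dictionary = index.dictionary
    q = query.lower() if dictionary.case_policy == "fold_lower" else query
    seen: set[str] = set()
    out: list[Candidate] = []
    for variant in delete_variants(q, index.max_distance):
        for word in index.variant_map.get(variant, ()):
            if word in seen:
                continue
            seen.add(word)
            dist = damerau_levenshtein(q, word)
            if dist <= index.max_distance:
                out.append(Candidate(term=word, distance=dist, count=dictionary.entries[word]))
    out.sort(key=lambda c: (c.distance, -c.count, c.term))
    return out
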