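"""Deterministic synthetic corpora.

Real surgical pathology records are restricted and the benchmark abstracts
are a large download, so every experiment in this package runs on generated
stand-ins that copy only *structure*, never patient content:

* SPR-like lines — "Organ , Location , OperationName : HistologicDiagnosis ,
  A × B × C cm" — with gold BIO tags under the SPR scheme.  Entities are
  short (length <= 3), matching the dominance of short entities in real
  pathology lines, and every tumor-size string parses under the tumor-size
  rule.
* Abstract-like prose with controlled collocations, so an n-gram context
  model has learnable signal.  The templates deliberately contain confusable
  word pairs ("lung"/"long", "wall"/"well") in which the *wrong* member is
  corpus-frequent and only sentence context identifies the right one: the
  scenario where context-aware correction must beat frequency-only
  correction.

Same spec and seed -> byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lexicon import TokenizedSentence, tokenize
from .ner import TaggedSentence

__all__ = [
    "FixtureSpec",
    "generate_spr_corpus",
    "generate_prose_corpus",
    "ORGANS",
    "LOCATIONS",
    "OPNAMES",
    "DIAGNOSES",
]

# Clinically plausible vocabulary tables; structure only, no real records.
ORGANS: tuple[tuple[str, ...], ...] = (
    ("lung",),
    ("bronchus",),
    ("pleura",),
    ("chest", "wall"),
)
LOCATIONS: tuple[tuple[str, ...], ...] = (
    ("left", "upper", "lobe"),
    ("left", "lower", "lobe"),
    ("right", "upper", "lobe"),
    ("right", "middle", "lobe"),
    ("right", "lower", "lobe"),
    ("lingula",),
    ("main", "bronchus"),
    ("apical", "segment"),
)
OPNAMES: tuple[tuple[str, ...], ...] = (
    ("lobectomy",),
    ("wedge", "resection"),
    ("pneumonectomy",),
    ("segmentectomy",),
    ("needle", "biopsy"),
    ("bronchial", "washing"),
)
DIAGNOSES: tuple[tuple[str, ...], ...] = (
    ("adenocarcinoma",),
    ("squamous", "cell", "carcinoma"),
    ("small", "cell", "carcinoma"),
    ("large", "cell", "carcinoma"),
    ("mucinous", "adenocarcinoma"),
    ("adenosquamous", "carcinoma"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the SPR-like generator."""

    n_sentences: int = 200
    seed: int = 7
    organs: tuple[tuple[str, ...], ...] = ORGANS
    locations: tuple[tuple[str, ...], ...] = LOCATIONS
    opnames: tuple[tuple[str, ...], ...] = OPNAMES
    diagnoses: tuple[tuple[str, ...], ...] = DIAGNOSES
    size_min: float = 0.3       # cm, smallest reported dimension
    size_max: float = 9.9       # cm, largest plausible lung-lesion axis
    times_sign_share: float = 0.8   # share of "×" vs ASCII "x" separators
    greatest_dim_share: float = 0.1  # share of "N cm IN GREATEST DIMENSION"
    typo_free: bool = True

    def __post_init__(self) -> None:
        for name in ("organs", "locations", "opnames", "diagnoses"):
            if not getattr(self, name):
                raise ValueError(f"vocabulary table {name!r} must be non-empty")


def _pick(rng: np.random.Generator, table: tuple[tuple[str, ...], ...]) -> tuple[str, ...]:
    return table[rng.integers(len(table))]


def _fmt_size(value: float) -> str:
    if value == int(value):
        return str(int(value))
    return f"{value:.1f}"


def _draw_sizes(rng: np.random.Generator, spec: FixtureSpec) -> list[str]:
    a = round(float(rng.uniform(spec.size_min, spec.size_max)), 1)
    b = round(float(rng.uniform(spec.size_min, a)), 1)
    c = round(float(rng.uniform(spec.size_min, b)), 1)
    return [_fmt_size(v) for v in (a, b, c)]


def generate_spr_corpus(spec: FixtureSpec) -> tuple[list[TaggedSentence], list[str]]:
    """Template-filled pathology lines with gold BIO labels.

    Returns the tagged sentences and the matching plain-text lines (tokens
    joined by single spaces, so re-tokenizing a line reproduces the tokens).
    """
    rng = np.random.default_rng(spec.seed)
    tagged: list[TaggedSentence] = []
    lines: list[str] = []
    for _ in range(spec.n_sentences):
        tokens: list[str] = []
        labels: list[str] = []

        def add_entity(words: tuple[str, ...], etype: str) -> None:
            for j, w in enumerate(words):
                tokens.append(w)
                labels.append(("B-" if j == 0 else "I-") + etype)

        def add_o(*words: str) -> None:
            for w in words:
                tokens.append(w)
                labels.append("O")

        add_entity(_pick(rng, spec.organs), "ORGAN")
        add_o(",")
        add_entity(_pick(rng, spec.locations), "LOCATION")
        add_o(",")
        add_entity(_pick(rng, spec.opnames), "OPNAME")
        add_o(":")
        add_entity(_pick(rng, spec.diagnoses), "HISTOLOGIC DIAGNOSIS")
        add_o(",")
        sizes = _draw_sizes(rng, spec)
        if rng.random() < spec.greatest_dim_share:
            # single-dimension variant: "N cm IN GREATEST DIMENSION"
            tokens.append(sizes[0])
            labels.append("B-TUMOR_SIZE")
            add_o("cm", "IN", "GREATEST", "DIMENSION")
        else:
            sep = "×" if rng.random() < spec.times_sign_share else "x"
            tokens.append(sizes[0])
            labels.append("B-TUMOR_SIZE")
            for s in sizes[1:]:
                add_o(sep, s)
            add_o("cm")
        sent = TaggedSentence(tuple(tokens), tuple(labels))
        tagged.append(sent)
        lines.append(" ".join(tokens))
    return tagged, lines


# --------------------------------------------------------------------------
# Prose generator
# --------------------------------------------------------------------------

# (weight, template) — {side} in {right,left}, {lobe} in {upper,lower,middle}.
# "long" and "well" are kept several times more frequent than their
# confusable counterparts "lung" and "wall".
_PROSE_TEMPLATES: tuple[tuple[float, str], ...] = (
    (0.12, "the {side} lung was examined and sectioned"),
    (0.30, "a long segment of tissue was submitted for review"),
    (0.10, "the {lobe} lobe contains a small firm mass"),
    (0.12, "the chest wall is intact and free of tumor"),
    (0.26, "the margins are well clear of carcinoma"),
    (0.10, "no residual carcinoma is identified in the specimen"),
)
_SIDES = ("right", "left")
_LOBES = ("upper", "lower", "middle")


def generate_prose_corpus(n_sentences: int, seed: int = 0) -> list[str]:
    """Markov-template prose over a closed vocabulary.

    Collocations such as "right lung" and "upper lobe" recur by construction,
    so a bidirectional n-gram model trained on the output can identify each
    confusable word from its sentence slot.
    """
    rng = np.random.default_rng(seed)
    weights = np.array([w for w, _ in _PROSE_TEMPLATES])
    weights = weights / weights.sum()
    lines: list[str] = []
    for _ in range(n_sentences):
        _, template = _PROSE_TEMPLATES[rng.choice(len(_PROSE_TEMPLATES), p=weights)]
        line = template.format(
            side=_SIDES[rng.integers(len(_SIDES))],
            lobe=_LOBES[rng.integers(len(_LOBES))],
        )
        lines.append(line)
    return lines


def prose_vocabulary() -> set[str]:
    """Every word the prose generator can emit."""
    vocab: set[str] = set(_SIDES) | set(_LOBES)
    for _, template in _PROSE_TEMPLATES:
        for tok in template.replace("{side}", "").replace("{lobe}", "").split():
            vocab.add(tok)
    return vocab


def tokenized(lines: list[str]) -> list[TokenizedSentence]:
    """Convenience: tokenize generated plain-text lines."""
    return [tokenize(line) for line in lines]
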