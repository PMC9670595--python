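"""BIO tagging utilities, CoNLL I/O, a baseline sequence tagger, and the
tumor-size post-processing rule for pathology report lines.

The headline tagger in the reference design is a fine-tuned transformer with a
per-token softmax head; at desk scale the in-repo baseline is a first-order
hidden Markov model over shape-normalized tokens with BIO-constrained Viterbi
decoding, which is near-perfect on the template-generated fixtures and needs
no external weights.  The transformer path is kept behind the same predict
contract as an optional backend.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TagScheme",
    "NCBI_SCHEME",
    "SPR_SCHEME",
    "TaggedSentence",
    "Entity",
    "FineTuneConfig",
    "read_conll",
    "write_conll",
    "decode_entities",
    "labels_from_entities",
    "validate_bio",
    "BaselineTagger",
    "train_baseline_tagger",
    "fine_tune_transformer",
    "extract_max_dimension",
]


@dataclass(frozen=True)
class TagScheme:
    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if "O" not in self.labels:
            raise ValueError("scheme must include the O label")
        for lab in self.labels:
            if lab != "O" and not (lab.startswith("B-") or lab.startswith("I-")):
                raise ValueError(f"bad BIO label: {lab!r}")

    def entity_types(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab != "O" and lab[2:] not in seen:
                seen.append(lab[2:])
        return seen


NCBI_SCHEME = TagScheme("ncbi", ("B-Disease", "I-Disease", "O"))
# TUMOR_SIZE appears only in Begin form: size entities are single-token.
SPR_SCHEME = TagScheme(
    "spr",
    (
        "B-ORGAN", "I-ORGAN",
        "B-LOCATION", "I-LOCATION",
        "B-OPNAME", "I-OPNAME",
        "B-HISTOLOGIC DIAGNOSIS", "I-HISTOLOGIC DIAGNOSIS",
        "B-TUMOR_SIZE",
        "O",
    ),
)

_SCHEMES = {"ncbi": NCBI_SCHEME, "spr": SPR_SCHEME}


def get_scheme(name: str) -> TagScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(_SCHEMES)}")


@dataclass(frozen=True)
class TaggedSentence:
    tokens: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError("tokens and labels must have equal length")


@dataclass(frozen=True)
class Entity:
    """Token span, 0-based start inclusive / end exclusive."""

    type: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("entity span must be non-empty")


@dataclass(frozen=True)
class FineTuneConfig:
    learning_rate: float = 3e-5
    epochs: int = 3
    max_sequence_length: int = 178
    batch_size: int = 16
    optimizer: str = "adam"
    activation: str = "softmax"


def validate_bio(labels: tuple[str, ...], policy: str = "strict") -> tuple[str, ...]:
    """Check the I-follows-B/I constraint.

    ``strict`` raises on a dangling I-X; ``repair`` promotes it to B-X
    (standard practice for model predictions).
    """
    if policy not in ("strict", "repair"):
        raise ValueError("policy must be 'strict' or 'repair'")
    out = list(labels)
    prev = "O"
    for i, lab in enumerate(out):
        if lab.startswith("I-"):
            etype = lab[2:]
            ok = prev != "O" and prev[2:] == etype
            if not ok:
                if policy == "strict":
                    raise ValueError(f"dangling {lab} at token {i}")
                out[i] = "B-" + etype
        prev = out[i]
    return tuple(out)


def read_conll(path, scheme: TagScheme, policy: str = "strict") -> list[TaggedSentence]:
    """Read token-per-line BIO data; blank lines separate sentences.

    Token and label are separated by a tab (preferred) or the first run of
    spaces; labels may themselves contain spaces (e.g. HISTOLOGIC DIAGNOSIS).
    """
    sentences: list[TaggedSentence] = []
    tokens: list[str] = []
    labels: list[str] = []
    valid = set(scheme.labels)

    def flush(lineno: int) -> None:
        if tokens:
            sentences.append(
                TaggedSentence(tuple(tokens), validate_bio(tuple(labels), policy))
            )
            tokens.clear()
            labels.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            if "\t" in line:
                tok, lab = line.split("\t", 1)
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise IOError(f"line {lineno}: expected 'token label', got {line!r}")
                tok, lab = parts
            if lab not in valid:
                raise IOError(
                    f"line {lineno}: label {lab!r} not in scheme {scheme.name!r}"
                )
            tokens.append(tok)
            labels.append(lab)
        flush(-1)
    return sentences


def write_conll(sentences: list[TaggedSentence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for tok, lab in zip(sent.tokens, sent.labels):
                fh.write(f"{tok}\t{lab}\n")
            fh.write("\n")


def decode_entities(sentence: TaggedSentence, policy: str = "strict") -> list[Entity]:
    """Maximal B-initiated runs of one type become entities; O contributes
    nothing.  A fresh B- always starts a new entity, so [B-X, B-X] yields two
    single-token entities."""
    labels = validate_bio(sentence.labels, policy)
    entities: list[Entity] = []
    start = None
    etype = None
    for i, lab in enumerate(labels):
        if lab.startswith("B-"):
            if start is not None:
                entities.append(_mk(sentence, etype, start, i))
            start, etype = i, lab[2:]
        elif lab.startswith("I-"):
            pass  # guaranteed continuation by validate_bio
        else:
            if start is not None:
                entities.append(_mk(sentence, etype, start, i))
            start = etype = None
    if start is not None:
        entities.append(_mk(sentence, etype, start, len(labels)))
    return entities


def _mk(sentence: TaggedSentence, etype: str, start: int, end: int) -> Entity:
    return Entity(type=etype, start=start, end=end,
                  text=" ".join(sentence.tokens[start:end]))


def labels_from_entities(n_tokens: int, entities: list[Entity]) -> tuple[str, ...]:
    """Inverse of decode_entities for non-overlapping entity lists."""
    labels = ["O"] * n_tokens
    for ent in sorted(entities, key=lambda e: e.start):
        if ent.end > n_tokens:
            raise ValueError("entity span exceeds sentence length")
        if any(labels[i] != "O" for i in range(ent.start, ent.end)):
            raise ValueError("overlapping entities")
        labels[ent.start] = "B-" + ent.type
        for i in range(ent.start + 1, ent.end):
            labels[i] = "I-" + ent.type
    return tuple(labels)


# --------------------------------------------------------------------------
# Baseline tagger: HMM with BIO-constrained decoding
# --------------------------------------------------------------------------

_NUM_RE = re.compile(r"\d+(?:\.\d+)?\Z")
_UNK = "<unk>"
_NUM = "<num>"


def _shape(token: str) -> str:
    if _NUM_RE.match(token):
        return _NUM
    return token.lower()


def _bio_ok(prev: str, cur: str) -> bool:
    if cur.startswith("I-"):
        return prev != "O" and prev != "<start>" and prev[2:] == cur[2:]
    return True


# Feature slots: token shapes at offsets -1, 0, +1 around the position.
_SLOTS = (-1, 0, 1)
_PAD = "<pad>"


@dataclass
class BaselineTagger:
    """Windowed naive-Bayes emissions with BIO-constrained Viterbi decoding.

    Per-position label scores combine add-one smoothed likelihoods of the
    previous, current, and next token shapes given the label; transitions are
    add-one smoothed label bigrams restricted to valid BIO moves, so every
    prediction is a valid sequence.  ``predict_marginals`` exposes the
    per-token softmax-style posterior over the scheme's labels via
    forward-backward.
    """

    scheme: TagScheme
    # feature_tables[label][slot] maps shape -> log-likelihood
    feature_tables: dict[str, dict[int, dict[str, float]]] = field(
        default_factory=dict, repr=False)
    transitions: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)
    vocab: set[str] = field(default_factory=set, repr=False)

    def _emit_logp(self, label: str, shapes: list[str], i: int) -> float:
        total = 0.0
        for slot in _SLOTS:
            j = i + slot
            shape = shapes[j] if 0 <= j < len(shapes) else _PAD
            table = self.feature_tables[label][slot]
            total += table.get(shape, table[_UNK])
        return total

    def _emission_matrix(self, shapes: list[str]) -> np.ndarray:
        labels = self.scheme.labels
        return np.array(
            [[self._emit_logp(lab, shapes, i) for lab in labels]
             for i in range(len(shapes))]
        )

    def predict(self, tokens: tuple[str, ...] | list[str]) -> TaggedSentence:
        tokens = tuple(tokens)
        if not tokens:
            return TaggedSentence((), ())
        labels = self.scheme.labels
        shapes = [_shape(t) for t in tokens]
        n, L = len(tokens), len(labels)
        emit = self._emission_matrix(shapes)
        score = np.full((n, L), -math.inf)
        back = np.zeros((n, L), dtype=int)
        for k, lab in enumerate(labels):
            if _bio_ok("<start>", lab):
                score[0, k] = self.transitions["<start>"].get(lab, -1e9) + emit[0, k]
        for i in range(1, n):
            for k, lab in enumerate(labels):
                best, arg = -math.inf, 0
                for j, prev in enumerate(labels):
                    if score[i - 1, j] == -math.inf or not _bio_ok(prev, lab):
                        continue
                    s = score[i - 1, j] + self.transitions[prev].get(lab, -1e9)
                    if s > best:
                        best, arg = s, j
                score[i, k] = best + emit[i, k] if best > -math.inf else -math.inf
                back[i, k] = arg
        k = int(np.argmax(score[n - 1]))
        out = [labels[k]]
        for i in range(n - 1, 0, -1):
            k = back[i, k]
            out.append(labels[k])
        out.reverse()
        return TaggedSentence(tokens, validate_bio(tuple(out), policy="repair"))

    def predict_marginals(self, tokens: tuple[str, ...] | list[str]) -> np.ndarray:
        """Per-token posterior P(label | sentence); rows sum to 1."""
        tokens = tuple(tokens)
        labels = self.scheme.labels
        n, L = len(tokens), len(labels)
        if n == 0:
            return np.zeros((0, L))
        shapes = [_shape(t) for t in tokens]
        emit = self._emission_matrix(shapes)
        trans = np.full((L, L), -1e9)
        for j, prev in enumerate(labels):
            for k, lab in enumerate(labels):
                if _bio_ok(prev, lab):
                    trans[j, k] = self.transitions[prev].get(lab, -1e9)
        start = np.array(
            [self.transitions["<start>"].get(lab, -1e9) if _bio_ok("<start>", lab) else -1e9
             for lab in labels]
        )
        fwd = np.zeros((n, L))
        fwd[0] = start + emit[0]
        for i in range(1, n):
            fwd[i] = emit[i] + _logsumexp_cols(fwd[i - 1][:, None] + trans)
        bwd = np.zeros((n, L))
        for i in range(n - 2, -1, -1):
            bwd[i] = _logsumexp_cols((trans + (emit[i + 1] + bwd[i + 1])[None, :]).T)
        log_post = fwd + bwd
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


def _logsumexp_cols(m: np.ndarray) -> np.ndarray:
    mx = m.max(axis=0)
    return mx + np.log(np.exp(m - mx).sum(axis=0))


def train_baseline_tagger(
    train: list[TaggedSentence],
    scheme: TagScheme,
    seed: int = 0,
) -> BaselineTagger:
    """Estimate windowed naive-Bayes emissions and label-bigram transitions
    from BIO-tagged sentences.

    The estimate is closed-form, so the seed only pins any future stochastic
    extension; training is deterministic regardless.
    """
    if not train:
        raise ValueError("empty training set")
    del seed  # closed-form estimation; kept for interface stability
    labels = scheme.labels
    vocab: set[str] = set()
    feat_counts: dict[str, dict[int, dict[str, int]]] = {
        lab: {slot: {} for slot in _SLOTS} for lab in labels
    }
    trans_counts: dict[str, dict[str, int]] = {lab: {} for lab in labels}
    trans_counts["<start>"] = {}
    for sent in train:
        shapes = [_shape(t) for t in sent.tokens]
        vocab.update(shapes)
        prev = "<start>"
        for i, lab in enumerate(sent.labels):
            if lab not in feat_counts:
                raise ValueError(f"label {lab!r} not in scheme {scheme.name!r}")
            for slot in _SLOTS:
                j = i + slot
                shape = shapes[j] if 0 <= j < len(shapes) else _PAD
                table = feat_counts[lab][slot]
                table[shape] = table.get(shape, 0) + 1
            trans_counts[prev][lab] = trans_counts[prev].get(lab, 0) + 1
            prev = lab
    V = len(vocab) + 2  # +pad, +unseen
    feature_tables: dict[str, dict[int, dict[str, float]]] = {}
    for lab in labels:
        feature_tables[lab] = {}
        for slot in _SLOTS:
            counts = feat_counts[lab][slot]
            total = sum(counts.values())
            table = {s: math.log((c + 1) / (total + V)) for s, c in counts.items()}
            table[_UNK] = math.log(1 / (total + V))
            feature_tables[lab][slot] = table
    transitions: dict[str, dict[str, float]] = {}
    for prev, row in trans_counts.items():
        total = sum(row.values())
        transitions[prev] = {
            lab: math.log((row.get(lab, 0) + 1) / (total + len(labels)))
            for lab in labels
        }
    return BaselineTagger(scheme=scheme, feature_tables=feature_tables,
                          transitions=transitions, vocab=vocab)


def fine_tune_transformer(train, config: FineTuneConfig, model_ref=None, backend=None):
    """Fine-tune an externally supplied pre-trained transformer tagger.

    No weights ship with this package; without a ``backend`` callable this
    raises with instructions.  A supplied backend receives (train, config,
    model_ref) and must return an object with the same ``predict`` contract
    as :class:`BaselineTagger`.
    """
    if backend is None:
        raise RuntimeError(
            "transformer fine-tuning needs external pre-trained weights and a "
            "training backend; pass backend=callable(train, config, model_ref) "
            "or use train_baseline_tagger for the offline default"
        )
    return backend(train, config, model_ref)


# --------------------------------------------------------------------------
# Tumor-size post-processing
# --------------------------------------------------------------------------

_NUMBER = r"\d+(?:\.\d+)?"
_SIZE_RE = re.compile(
    rf"({_NUMBER})(?:\s*[×x]\s*({_NUMBER}))?(?:\s*[×x]\s*({_NUMBER}))?\s*(cm\b)?",
    re.IGNORECASE,
)


def extract_max_dimension(text: str) -> float | None:
    """Largest dimension, in cm, from a tumor-size expression.

    Handles "A × B × C cm" (two or three numbers, × or x, unit optional) and
    single-number forms like "1.2 cm IN GREATEST DIMENSION" (unit required
    when only one number is present, so bare counts are not mistaken for
    sizes).  Returns None when nothing matches.
    """
    best: float | None = None
    for m in _SIZE_RE.finditer(text):
        nums = [g for g in m.group(1, 2, 3) if g is not None]
        has_unit = m.group(4) is not None
        if len(nums) == 1 and not has_unit:
            continue
        value = max(float(n) for n in nums)
        if best is None or value > best:
            best = value
    return best
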