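"""Context scoring of correction candidates at a masked sentence position.

The reference design scores a candidate c for slot i of sentence s_1..s_t by
masking the slot and asking a language model for P(c | s_1..s_{i-1}, [MASK],
s_{i+1}..s_t).  Two backends satisfy one contract:

* ``NgramBackend`` — the tested, offline default.  It approximates the
  bidirectional conditioning of a masked language model with two additively
  smoothed n-gram models, one reading left-to-right and one right-to-left;
  a candidate's raw score is the mean of the two directional conditional
  log-probabilities at the masked slot.
* ``TransformerMLMBackend`` — a thin adapter around externally supplied
  pre-trained masked-LM weights.  It is optional: constructing it without a
  loader raises :class:`BackendUnavailableError` with enabling instructions.

``score_candidates`` renormalizes either backend's raw log scores over the
candidate set (softmax), so the context score is a probability distribution
over the candidates and commensurate with the frequency score it is later
combined with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .lexicon import TokenizedSentence

__all__ = [
    "MaskedQuery",
    "SoftmaxDistribution",
    "ContextScorer",
    "NgramBackend",
    "TransformerMLMBackend",
    "BackendUnavailableError",
    "softmax",
    "train_ngram_backend",
    "score_candidates",
]

_BOS = "<s>"
_EOS = "</s>"


class BackendUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaskedQuery:
    """A sentence with one masked slot (the typo position)."""

    tokens: tuple[str, ...]
    target_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.target_index < len(self.tokens):
            raise ValueError(
                f"target_index {self.target_index} out of range for "
                f"{len(self.tokens)} tokens"
            )


@dataclass(frozen=True)
class SoftmaxDistribution:
    raw_scores: tuple[float, ...]
    probabilities: tuple[float, ...]


def softmax(raw_scores: Sequence[float]) -> SoftmaxDistribution:
    """y_k = exp(a_k) / sum_i exp(a_i), stabilized by max subtraction."""
    a = np.asarray(raw_scores, dtype=float)
    if a.size == 0:
        raise ValueError("softmax of an empty vector")
    if not np.all(np.isfinite(a)):
        raise ValueError("softmax requires finite scores")
    e = np.exp(a - a.max())
    p = e / e.sum()
    return SoftmaxDistribution(raw_scores=tuple(a.tolist()), probabilities=tuple(p.tolist()))


class ContextScorer(Protocol):
    """Contract: one finite log-probability per candidate, depending only on
    (tokens, target_index, candidate strings)."""

    def raw_scores(self, query: MaskedQuery, candidates: Sequence[str]) -> list[float]:
        ...


class _DirectionalNgram:
    """Additively smoothed order-k model: P(w | previous k-1 tokens)."""

    def __init__(self, order: int, smoothing: float) -> None:
        self.order = order
        self.smoothing = smoothing
        self.context_counts: dict[tuple[str, ...], int] = {}
        self.joint_counts: dict[tuple[str, ...], int] = {}
        self.vocab: set[str] = set()

    def observe(self, tokens: Sequence[str]) -> None:
        padded = [_BOS] * (self.order - 1) + list(tokens) + [_EOS]
        self.vocab.update(tokens)
        for i in range(self.order - 1, len(padded)):
            ctx = tuple(padded[i - self.order + 1:i])
            self.context_counts[ctx] = self.context_counts.get(ctx, 0) + 1
            joint = ctx + (padded[i],)
            self.joint_counts[joint] = self.joint_counts.get(joint, 0) + 1

    def logprob(self, word: str, context: Sequence[str]) -> float:
        ctx = tuple(context[-(self.order - 1):])
        if len(ctx) < self.order - 1:
            ctx = (_BOS,) * (self.order - 1 - len(ctx)) + ctx
        v = len(self.vocab) + 2  # +BOS/EOS-ish unseen mass
        num = self.joint_counts.get(ctx + (word,), 0) + self.smoothing
        den = self.context_counts.get(ctx, 0) + self.smoothing * v
        return math.log(num) - math.log(den)


@dataclass
class NgramBackend:
    """Bidirectional n-gram context scorer (the offline default)."""

    order: int = 3
    smoothing: float = 0.01
    forward: _DirectionalNgram = field(init=False, repr=False)
    backward: _DirectionalNgram = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.smoothing <= 0:
            raise ValueError("smoothing must be positive")
        self.forward = _DirectionalNgram(self.order, self.smoothing)
        self.backward = _DirectionalNgram(self.order, self.smoothing)

    def train(self, corpus: Iterable[TokenizedSentence | Sequence[str]]) -> "NgramBackend":
        n = 0
        for sent in corpus:
            tokens = list(sent.tokens if isinstance(sent, TokenizedSentence) else sent)
            self.forward.observe(tokens)
            self.backward.observe(list(reversed(tokens)))
            n += 1
        if n == 0:
            raise ValueError("cannot train on an empty corpus")
        return self

    def raw_scores(self, query: MaskedQuery, candidates: Sequence[str]) -> list[float]:
        i = query.target_index
        left = list(query.tokens[:i])
        right_rev = list(reversed(query.tokens[i + 1:]))
        out = []
        for cand in candidates:
            fwd = self.forward.logprob(cand, left)
            bwd = self.backward.logprob(cand, right_rev)
            out.append(0.5 * (fwd + bwd))
        return out

    # --- serialization: plain TSV counts, reloadable -----------------------
    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#order\t{self.order}\n#smoothing\t{self.smoothing}\n")
            for tag, model in (("F", self.forward), ("B", self.backward)):
                for w in sorted(model.vocab):
                    fh.write(f"{tag}\tV\t{w}\n")
                for ctx, c in sorted(model.context_counts.items()):
                    fh.write(f"{tag}\tC\t{' '.join(ctx)}\t{c}\n")
                for joint, c in sorted(model.joint_counts.items()):
                    fh.write(f"{tag}\tJ\t{' '.join(joint)}\t{c}\n")

    @classmethod
    def load(cls, path: str | Path) -> "NgramBackend":
        with open(path, encoding="utf-8") as fh:
            order = smoothing = None
            rows = []
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#order"):
                    order = int(line.split("\t")[1])
                elif line.startswith("#smoothing"):
                    smoothing = float(line.split("\t")[1])
                elif line:
                    rows.append(line.split("\t"))
        if order is None or smoothing is None:
            raise IOError("missing ngram model header")
        backend = cls(order=order, smoothing=smoothing)
        for row in rows:
            tag, kind = row[0], row[1]
            model = backend.forward if tag == "F" else backend.backward
            if kind == "V":
                model.vocab.add(row[2])
            elif kind == "C":
                model.context_counts[tuple(row[2].split(" "))] = int(row[3])
            elif kind == "J":
                model.joint_counts[tuple(row[2].split(" "))] = int(row[3])
        return backend


def train_ngram_backend(
    corpus: Iterable[TokenizedSentence | Sequence[str]],
    order: int = 3,
    smoothing: float = 0.01,
) -> NgramBackend:
    """Train the bidirectional n-gram backend on a tokenized corpus."""
    return NgramBackend(order=order, smoothing=smoothing).train(corpus)


class TransformerMLMBackend:
    """Adapter for an externally supplied pre-trained masked language model.

    ``model_loader`` must return an object with a
    ``score(tokens, target_index, candidates) -> list[float]`` method giving
    per-candidate log-probabilities (multi-subword candidates are the loader's
    responsibility: one mask per subword piece, log-probabilities averaged).
    No weights ship with this package and none are downloaded.
    """

    def __init__(self, model_ref: str | None = None, model_loader=None) -> None:
        if model_loader is None:
            raise BackendUnavailableError(
                "transformer MLM backend needs externally supplied weights: "
                "pass model_loader=... returning an object with a "
                ".score(tokens, target_index, candidates) method "
                f"(model_ref={model_ref!r}); the offline default is the "
                "ngram backend"
            )
        self._model = model_loader(model_ref)

    def raw_scores(self, query: MaskedQuery, candidates: Sequence[str]) -> list[float]:
        scores = self._model.score(list(query.tokens), query.target_index, list(candidates))
        out = [float(s) for s in scores]
        if len(out) != len(candidates) or not all(math.isfinite(s) for s in out):
            raise ValueError("MLM backend returned malformed scores")
        return out


def score_candidates(
    scorer: ContextScorer,
    query: MaskedQuery,
    candidates: Sequence[str],
) -> dict[str, float]:
    """Backend log scores renormalized over the candidate set.

    The returned probabilities sum to one; the ranking is invariant to any
    positive rescaling of the backend's raw scores because the softmax is
    monotone.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    try:
        raw = scorer.raw_scores(query, candidates)
    except Exception as exc:
        raise RuntimeError(
            f"context backend failed for candidates {list(candidates)!r} "
            f"at slot {query.target_index}"
        ) from exc
    dist = softmax(raw)
    return dict(zip(candidates, dist.probabilities))
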