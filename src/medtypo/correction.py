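"""Candidate ranking and typo correction.

Each candidate w for a flagged token gets

    FinalScore(w) = lambda * FrequencyScore(w) + (1 - lambda) * ContextScore(w)

where FrequencyScore is the candidate's dictionary count normalized over the
candidate set and ContextScore is the masked-slot probability from the context
backend, also normalized over the candidate set.  Both terms live on [0, 1]
over the same support, so lambda in [0, 1] interpolates between pure
frequency ranking (lambda = 1) and pure context ranking (lambda = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .candidates import Candidate, DeleteIndex, generate_candidates
from .context_scoring import ContextScorer, MaskedQuery, score_candidates
from .lexicon import TokenizedSentence, is_word_token

__all__ = [
    "CorrectionConfig",
    "ScoredCandidate",
    "CorrectionResult",
    "frequency_score",
    "final_score",
    "correct_token",
    "correct_sentence",
    "correct_corpus",
]


@dataclass(frozen=True)
class CorrectionConfig:
    lambda_weight: float = 0.5
    max_distance: int = 2
    oov_only: bool = True
    min_token_length: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")


@dataclass(frozen=True)
class ScoredCandidate:
    term: str
    distance: int
    count: int
    frequency_score: float
    context_score: float
    final_score: float


@dataclass(frozen=True)
class CorrectionResult:
    sentence_index: int
    token_index: int
    original: str
    chosen: str
    changed: bool
    candidates: tuple[ScoredCandidate, ...] = field(default=())


def frequency_score(candidates: list[Candidate]) -> dict[str, float]:
    """Relative frequency of each candidate within the candidate set."""
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    total = sum(c.count for c in candidates)
    if total <= 0:
        raise ValueError("candidate counts must be positive")
    return {c.term: c.count / total for c in candidates}


def final_score(freq: float, context: float, lambda_weight: float) -> float:
    """Convex combination of the two component scores."""
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValueError("lambda_weight must lie in [0, 1]")
    if not (0.0 <= freq <= 1.0 and 0.0 <= context <= 1.0):
        raise ValueError("component scores must lie in [0, 1]")
    return lambda_weight * freq + (1.0 - lambda_weight) * context


def _match_case(template: str, word: str) -> str:
    """Give ``word`` the capitalization pattern of ``template``."""
    if template.isupper() and len(template) > 1:
        return word.upper()
    if template[:1].isupper():
        return word[:1].upper() + word[1:]
    return word


def correct_token(
    sentence: TokenizedSentence,
    index: int,
    config: CorrectionConfig,
    delete_index: DeleteIndex,
    scorer: ContextScorer,
    sentence_index: int = 0,
) -> CorrectionResult:
    """Score and (possibly) replace one token against its original sentence
    context.

    Tokens are skipped — returned unchanged with an empty candidate list —
    when they are non-alphabetic, shorter than the configured minimum, or
    already in the dictionary under ``oov_only``.  Ties on the final score
    break by smaller edit distance, then larger raw count, then
    lexicographically, so output is deterministic.
    """
    token = sentence.tokens[index]
    unchanged = CorrectionResult(
        sentence_index=sentence_index,
        token_index=index,
        original=token,
        chosen=token,
        changed=False,
    )
    if len(token) < config.min_token_length or not is_word_token(token):
        return unchanged
    dictionary = delete_index.dictionary
    if config.oov_only and token in dictionary:
        return unchanged

    cands = generate_candidates(token, delete_index)
    if not cands:
        return unchanged

    freq = frequency_score(cands)
    query = MaskedQuery(tokens=sentence.tokens, target_index=index)
    ctx = score_candidates(scorer, query, [c.term for c in cands])

    lam = config.lambda_weight
    scored = [
        ScoredCandidate(
            term=c.term,
            distance=c.distance,
            count=c.count,
            frequency_score=freq[c.term],
            context_score=ctx[c.term],
            final_score=final_score(freq[c.term], ctx[c.term], lam),
        )
        for c in cands
    ]
    scored.sort(key=lambda s: (-s.final_score, s.distance, -s.count, s.term))
    best = scored[0]
    chosen = _match_case(token, best.term)
    return CorrectionResult(
        sentence_index=sentence_index,
        token_index=index,
        original=token,
        chosen=chosen,
        changed=chosen != token,
        candidates=tuple(scored),
    )


def correct_sentence(
    sentence: TokenizedSentence,
    config: CorrectionConfig,
    delete_index: DeleteIndex,
    scorer: ContextScorer,
    sentence_index: int = 0,
) -> tuple[TokenizedSentence, list[CorrectionResult]]:
    """Correct every token independently against the original (uncorrected)
    sentence context."""
    results = [
        correct_token(sentence, i, config, delete_index, scorer, sentence_index)
        for i in range(len(sentence.tokens))
    ]
    tokens = tuple(r.chosen for r in results)
    return TokenizedSentence(tokens=tokens, raw=" ".join(tokens)), results


def correct_corpus(
    sentences: list[TokenizedSentence],
    config: CorrectionConfig,
    delete_index: DeleteIndex,
    scorer: ContextScorer,
) -> tuple[list[TokenizedSentence], list[CorrectionResult]]:
    corrected: list[TokenizedSentence] = []
    results: list[CorrectionResult] = []
    for si, sent in enumerate(sentences):
        try:
            new_sent, sent_results = correct_sentence(sent, config, delete_index, scorer, si)
        except Exception as exc:
            raise RuntimeError(f"correction failed at sentence {si}") from exc
        corrected.append(new_sent)
        results.extend(sent_results)
    return corrected, results
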