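"""Evaluation harnesses.

Correction is scored as per-token restoration: every injected typo is either
restored (tp) or not (fn), and precision is additionally penalized by wrong
fixes and by spurious changes of clean tokens (fp).  NER is scored at the
entity level with exact span and type matching, the strictest common
convention, alongside token accuracy.  The sweep harness measures how entity
F1 degrades as the injected error rate grows and how much correction recovers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .correction import CorrectionConfig, correct_corpus
from .error_model import CorruptionRecord, ErrorType, corrupt_corpus
from .lexicon import TokenizedSentence
from .ner import BaselineTagger, TaggedSentence, decode_entities

__all__ = [
    "PRF",
    "CorrectionEvalReport",
    "NEREvalReport",
    "SweepRow",
    "evaluate_correction",
    "evaluate_ner",
    "sweep_error_rate",
]


@dataclass
class PRF:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def support(self) -> int:
        return self.tp + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "support": self.support,
        }


@dataclass
class CorrectionEvalReport:
    overall: PRF
    per_error_type: dict[ErrorType, PRF]
    spurious_changes: int

    @property
    def support(self) -> int:
        return self.overall.support

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            "per_error_type": {t.value: p.as_dict() for t, p in self.per_error_type.items()},
            "spurious_changes": self.spurious_changes,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def evaluate_correction(
    gold: list[TokenizedSentence],
    records: list[CorruptionRecord],
    corrected: list[TokenizedSentence],
) -> CorrectionEvalReport:
    """Token-level restoration metrics over aligned gold/corrected corpora.

    tp: a corrupted token whose output equals the gold token.  fn: a corrupted
    token whose output differs from gold (left broken or mis-fixed).  fp: any
    output token differing from gold where the system itself made the wrong
    change — a mis-fix of a typo or a spurious edit of a clean token.
    """
    if len(gold) != len(corrected):
        raise ValueError(
            f"corpus length mismatch: gold {len(gold)} vs corrected {len(corrected)}"
        )
    rec_map: dict[tuple[int, int], CorruptionRecord] = {}
    for r in records:
        rec_map[(r.sentence_index, r.token_index)] = r

    overall = PRF()
    per_type = {t: PRF() for t in ErrorType}
    spurious = 0
    for si, (g, c) in enumerate(zip(gold, corrected)):
        if len(g.tokens) != len(c.tokens):
            raise ValueError(
                f"sentence {si}: token count mismatch "
                f"({len(g.tokens)} gold vs {len(c.tokens)} corrected)"
            )
        for ti, (gt, ct) in enumerate(zip(g.tokens, c.tokens)):
            rec = rec_map.get((si, ti))
            if rec is not None:
                bucket = per_type[rec.error_type]
                if ct == gt:
                    overall.tp += 1
                    bucket.tp += 1
                else:
                    overall.fn += 1
                    bucket.fn += 1
                    if ct != rec.corrupted:  # mis-fix, not merely left broken
                        overall.fp += 1
                        bucket.fp += 1
            elif ct != gt:  # clean token spuriously changed
                overall.fp += 1
                spurious += 1
    return CorrectionEvalReport(overall=overall, per_error_type=per_type,
                                spurious_changes=spurious)


@dataclass
class NEREvalReport:
    micro: PRF
    per_label: dict[str, PRF]
    token_accuracy: float
    n_tokens: int

    def as_dict(self) -> dict:
        return {
            "micro": self.micro.as_dict(),
            "per_label": {k: v.as_dict() for k, v in self.per_label.items()},
            "token_accuracy": self.token_accuracy,
            "n_tokens": self.n_tokens,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def evaluate_ner(
    gold: list[TaggedSentence],
    pred: list[TaggedSentence],
) -> NEREvalReport:
    """Entity-level precision/recall/F1 (exact span, exact type) plus token
    accuracy.  Predictions are BIO-repaired before decoding; gold must be
    strictly valid."""
    if len(gold) != len(pred):
        raise ValueError(f"corpus length mismatch: {len(gold)} vs {len(pred)}")
    micro = PRF()
    per_label: dict[str, PRF] = {}
    correct_tokens = 0
    n_tokens = 0
    for si, (g, p) in enumerate(zip(gold, pred)):
        if len(g.tokens) != len(p.tokens):
            raise ValueError(f"sentence {si}: token count mismatch")
        n_tokens += len(g.tokens)
        correct_tokens += sum(gl == pl for gl, pl in zip(g.labels, p.labels))
        g_ents = {(e.type, e.start, e.end) for e in decode_entities(g, policy="strict")}
        p_ents = {(e.type, e.start, e.end) for e in decode_entities(p, policy="repair")}
        for etype, *_ in g_ents | p_ents:
            per_label.setdefault(etype, PRF())
        for ent in p_ents:
            if ent in g_ents:
                micro.tp += 1
                per_label[ent[0]].tp += 1
            else:
                micro.fp += 1
                per_label[ent[0]].fp += 1
        for ent in g_ents - p_ents:
            micro.fn += 1
            per_label[ent[0]].fn += 1
    accuracy = correct_tokens / n_tokens if n_tokens else 0.0
    return NEREvalReport(micro=micro, per_label=per_label,
                         token_accuracy=accuracy, n_tokens=n_tokens)


@dataclass
class SweepRow:
    rate: float
    n_errors: int
    f1_with_typos: float
    f1_after_correction: float
    seed: int


def sweep_error_rate(
    corpus: list[TaggedSentence],
    rates: list[float],
    tagger: BaselineTagger,
    seed: int,
    corrector: tuple[CorrectionConfig, object, object] | None = None,
) -> list[SweepRow]:
    """For each error rate: corrupt the test corpus, tag it, and (optionally)
    correct it and tag again.

    ``corrector`` is a (config, delete_index, scorer) triple; when None the
    after-correction column repeats the with-typos value.  Rows come back in
    rate order; each rate gets an independent, reproducible substream of the
    base seed.
    """
    gold_sents = [TokenizedSentence(s.tokens, " ".join(s.tokens)) for s in corpus]
    rows: list[SweepRow] = []
    for k, rate in enumerate(sorted(rates)):
        if not 0 <= rate < 1:
            raise ValueError(f"rate {rate} outside [0, 1)")
        try:
            rng = np.random.default_rng([seed, k])
            corrupted, records = corrupt_corpus(gold_sents, rate=rate, rng=rng)
            pred_typos = [tagger.predict(s.tokens) for s in corrupted]
            gold_tagged = [
                TaggedSentence(c.tokens, g.labels) for c, g in zip(corrupted, corpus)
            ]
            f1_typos = evaluate_ner(gold_tagged, pred_typos).micro.f1
            if corrector is not None and rate > 0:
                config, delete_index, scorer = corrector
                fixed, _ = correct_corpus(corrupted, config, delete_index, scorer)
                pred_fixed = [tagger.predict(s.tokens) for s in fixed]
                gold_fixed = [
                    TaggedSentence(c.tokens, g.labels) for c, g in zip(fixed, corpus)
                ]
                f1_fixed = evaluate_ner(gold_fixed, pred_fixed).micro.f1
            else:
                f1_fixed = f1_typos
        except Exception as exc:
            raise RuntimeError(f"sweep failed at rate {rate}") from exc
        rows.append(SweepRow(rate=rate, n_errors=len(records),
                             f1_with_typos=f1_typos,
                             f1_after_correction=f1_fixed, seed=seed))
    return rows
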