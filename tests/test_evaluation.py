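import numpy as np
import pytest

import medtypo as m
from medtypo.error_model import CorruptionRecord, ErrorType
from medtypo.evaluation import evaluate_correction, evaluate_ner, sweep_error_rate
from medtypo.lexicon import TokenizedSentence
from medtypo.ner import SPR_SCHEME, TaggedSentence, train_baseline_tagger


def _sent(*tokens):
    return TokenizedSentence(tuple(tokens), " ".join(tokens))


def _rec(si, ti, orig, corr, etype=ErrorType.DELETE):
    return CorruptionRecord(si, ti, orig, corr, etype, 1)


def test_perfect_restoration_scores_one():
    gold = [_sent("right", "lung")]
    records = [_rec(0, 0, "right", "righ")]
    report = evaluate_correction(gold, records, [_sent("right", "lung")])
    o = report.overall
    assert (o.precision, o.recall, o.f1) == (1.0, 1.0, 1.0)
    assert o.support == 1


def test_system_that_changes_nothing():
    gold = [_sent("right", "lung")]
    records = [_rec(0, 0, "right", "righ")]
    report = evaluate_correction(gold, records, [_sent("righ", "lung")])
    o = report.overall
    assert o.tp == 0 and o.fp == 0 and o.recall == 0.0
    assert o.precision == 0.0  # degenerate denominator convention


def test_hand_counted_ten_token_fixture():
    """4 typos: 3 restored, 1 mis-corrected; plus 1 clean token wrongly
    changed -> tp=3, fn=1, fp=2, P=0.6, R=0.75, F1~0.667."""
    gold = [_sent(*"abcde"), _sent(*"fghij")]
    records = [
        _rec(0, 0, "a", "a1", ErrorType.INSERT),
        _rec(0, 1, "b", "b1", ErrorType.DELETE),
        _rec(1, 0, "f", "f1", ErrorType.REPLACE),
        _rec(1, 1, "g", "g1", ErrorType.TRANSPOSE),
    ]
    corrected = [
        _sent("a", "b", "c", "d", "e"),       # both typos restored
        _sent("f", "X", "h", "i", "Z"),        # g mis-fixed, j spuriously changed
    ]
    report = evaluate_correction(gold, records, corrected)
    o = report.overall
    assert (o.tp, o.fn, o.fp) == (3, 1, 2)
    assert o.precision == pytest.approx(0.6)
    assert o.recall == pytest.approx(0.75)
    assert o.f1 == pytest.approx(2 / 3, abs=1e-3)
    assert report.spurious_changes == 1
    assert report.per_error_type[ErrorType.TRANSPOSE].fn == 1
    assert report.per_error_type[ErrorType.INSERT].tp == 1


def test_support_identity_and_f1_consistency(prose_resources):
    gold = [m.tokenize(l) for l in m.generate_prose_corpus(40, seed=6)]
    corrupted, records = m.corrupt_corpus(gold, rate=0.12,
                                          rng=np.random.default_rng(0))
    fixed, _ = m.correct_corpus(corrupted, m.CorrectionConfig(),
                                prose_resources["index"], prose_resources["lm"])
    report = evaluate_correction(gold, records, fixed)
    o = report.overall
    assert o.tp + o.fn == len(records) == o.support
    p, r = o.precision, o.recall
    assert o.f1 == pytest.approx(2 * p * r / (p + r) if p + r else 0.0)
    per_type_support = sum(v.support for v in report.per_error_type.values())
    assert per_type_support == o.support


def test_alignment_mismatch_is_an_error():
    with pytest.raises(ValueError, match="mismatch"):
        evaluate_correction([_sent("a")], [], [_sent("a"), _sent("b")])
    with pytest.raises(ValueError, match="sentence 0"):
        evaluate_correction([_sent("a", "b")], [], [_sent("a")])


# ---------------------------------------------------------------------------
# NER evaluation
# ---------------------------------------------------------------------------

def test_identical_gold_and_pred():
    sents = [TaggedSentence(("left", "lung", "."), ("B-ORGAN", "I-ORGAN", "O"))]
    report = evaluate_ner(sents, sents)
    assert report.micro.f1 == 1.0 and report.token_accuracy == 1.0


def test_all_outside_prediction_has_zero_recall():
    gold = [TaggedSentence(("left", "lung"), ("B-ORGAN", "I-ORGAN"))]
    pred = [TaggedSentence(("left", "lung"), ("O", "O"))]
    report = evaluate_ner(gold, pred)
    assert report.micro.recall == 0.0
    assert report.per_label["ORGAN"].recall == 0.0


def test_span_mismatch_counts_both_fp_and_fn():
    gold = [TaggedSentence(("left", "lung"), ("B-ORGAN", "I-ORGAN"))]
    pred = [TaggedSentence(("left", "lung"), ("B-ORGAN", "O"))]
    report = evaluate_ner(gold, pred)
    assert report.micro.f1 == 0.0
    assert report.micro.fp == 1 and report.micro.fn == 1


def _reference_chunks(labels):
    """Independent chunk extraction: scan the label strings directly."""
    chunks = []
    i = 0
    while i < len(labels):
        if labels[i].startswith("B-"):
            etype = labels[i][2:]
            j = i + 1
            while j < len(labels) and labels[j] == "I-" + etype:
                j += 1
            chunks.append((etype, i, j))
            i = j
        else:
            i += 1
    return set(chunks)


def test_ner_evaluator_matches_reference_on_random_sequences():
    """Pooled tp/fp/fn agree with an independent chunk evaluator on 50
    random valid BIO sequences."""
    rng = np.random.default_rng(123)
    labels = SPR_SCHEME.labels
    tp = fp = fn = 0
    gold_sents, pred_sents = [], []
    for _ in range(50):
        n = int(rng.integers(1, 15))

        def random_valid():
            out, prev = [], "O"
            for _ in range(n):
                choices = [l for l in labels
                           if not l.startswith("I-")
                           or (prev != "O" and prev[2:] == l[2:])]
                lab = choices[rng.integers(len(choices))]
                out.append(lab)
                prev = lab
            return tuple(out)

        g, p = random_valid(), random_valid()
        toks = tuple(["w"] * n)
        gold_sents.append(TaggedSentence(toks, g))
        pred_sents.append(TaggedSentence(toks, p))
        gc, pc = _reference_chunks(g), _reference_chunks(p)
        tp += len(gc & pc)
        fp += len(pc - gc)
        fn += len(gc - pc)
    report = evaluate_ner(gold_sents, pred_sents)
    assert (report.micro.tp, report.micro.fp, report.micro.fn) == (tp, fp, fn)


def test_per_label_supports_sum_to_total_gold_entities():
    tagged, _ = m.generate_spr_corpus(m.FixtureSpec(n_sentences=30, seed=5))
    pred = [TaggedSentence(s.tokens, tuple(["O"] * len(s.tokens))) for s in tagged]
    report = evaluate_ner(tagged, pred)
    total_gold = sum(len(m.decode_entities(s)) for s in tagged)
    assert sum(v.support for v in report.per_label.values()) == total_gold


# ---------------------------------------------------------------------------
# Sweep harness
# ---------------------------------------------------------------------------

def test_sweep_rate_zero_equals_clean_f1(spr_resources):
    tagged = spr_resources["tagged"]
    split = int(0.8 * len(tagged))
    tagger = train_baseline_tagger(tagged[:split], SPR_SCHEME, seed=7)
    test = tagged[split:]
    clean_pred = [tagger.predict(s.tokens) for s in test]
    clean_f1 = evaluate_ner(test, clean_pred).micro.f1
    (row,) = sweep_error_rate(test, [0.0], tagger, seed=1)
    assert row.f1_with_typos == pytest.approx(clean_f1)
    assert row.f1_after_correction == pytest.approx(clean_f1)


def test_sweep_is_deterministic(spr_resources):
    tagged = spr_resources["tagged"]
    split = int(0.8 * len(tagged))
    tagger = train_baseline_tagger(tagged[:split], SPR_SCHEME, seed=7)
    corrector = (m.CorrectionConfig(), spr_resources["index"], spr_resources["lm"])
    a = sweep_error_rate(tagged[split:], [0.05, 0.10], tagger, seed=21,
                         corrector=corrector)
    b = sweep_error_rate(tagged[split:], [0.05, 0.10], tagger, seed=21,
                         corrector=corrector)
    assert a == b


def test_sweep_rejects_bad_rate(spr_resources):
    tagged = spr_resources["tagged"]
    tagger = train_baseline_tagger(tagged[:10], SPR_SCHEME, seed=7)
    with pytest.raises(ValueError):
        sweep_error_rate(tagged[:5], [1.5], tagger, seed=0)
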