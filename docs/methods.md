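# Methods

## Problem setting

Non-word typos in clinical free text (a token like "wedgoe" that is not a
word) corrupt the surface forms that entity extraction depends on. The
package implements a correction pipeline that ranks dictionary candidates for
each out-of-vocabulary token by combining how common a candidate is with how
well it fits the masked sentence slot, plus the machinery to measure the
effect: a typo injector with known provenance, token-level restoration
metrics, and an entity-level NER harness.

## Tokenization and dictionary

Tokens are maximal runs matched after NFC normalization: words with internal
hyphens/apostrophes, numbers with an optional decimal part, or single
symbols. This keeps "2.1" whole and makes "×" its own token, which the
tumor-size rule needs. The dictionary holds alphabetic tokens of length ≥ 2
whose corpus count reaches `min_count` (default 20 — a word seen exactly 20
times is kept; only strictly rarer words are dropped). Words are case-folded
by default; both choices are configurable because neither is forced by the
problem. Serialization is a two-column TSV sorted by descending count then
lexicographically, so files diff deterministically.

## Candidate generation

The delete-neighborhood index maps every string reachable from a dictionary
word by up to `max_distance` deletions back to that word. Lookup intersects
the query's own delete variants with the index and then verifies each hit
with the restricted Damerau–Levenshtein (optimal string alignment) distance.
The restricted variant is used because an adjacent transposition is one
atomic injected error type and must cost 1, not 2. Verification is required:
the delete trick overgenerates (e.g. at distance 2 for substitution-heavy
pairs) but never undergenerates, since two strings within OSA distance d
share a common descendant after at most d deletions each. `max_distance`
defaults to 2: injected errors are single edits, and the slack tolerates
pre-existing noise. Candidates sort by (distance, −count, term), which is
also the tie-break order after scoring.

## Scoring and correction

* FrequencyScore: candidate count / total count over the candidate set.
* ContextScore: the context backend's log-scores softmax-renormalized over
  the candidate set.

Both live on [0, 1] over the same support, so
`FinalScore = λ·FrequencyScore + (1−λ)·ContextScore` is a convex combination
of commensurate quantities. λ defaults to 0.5 — a neutral prior between the
two signals; all direction-style results here are reported against the λ = 1
and λ = 0 reductions rather than a tuned value. Renormalizing the context
probability over candidates (rather than using the raw masked-vocabulary
probability) is a deliberate choice to keep the two scales comparable and is
configurable in spirit: the backend also exposes raw log-scores.

Only out-of-vocabulary alphabetic tokens of length ≥ 2 are corrected by
default (`oov_only=True`): the injected errors are non-word errors, and
re-ranking valid words risks precision-destroying false alarms. The chosen
candidate inherits the original token's capitalization pattern (initial
capital, all-caps). Every token is scored against the original, uncorrected
sentence context, so correction order cannot feed back into scoring.

## Context backends

The tested default is a bidirectional n-gram model: an order-k (default 3)
left-to-right model and an identical right-to-left model, each additively
smoothed (default constant 0.01, guaranteeing finite scores for unseen
words), with sentence-boundary padding. A candidate's raw score at slot i is
the mean of its forward log-probability given the preceding context and its
backward log-probability given the following context — a desk-scale
approximation of a masked language model's bidirectional conditioning. A
transformer MLM backend implements the same contract (one finite log-score
per candidate, pure in its inputs) over externally supplied weights; it is
optional, raises a descriptive error when no model loader is given, and is
exercised in tests only through a stub, never through downloaded weights.
Multi-subword candidates are the loader's responsibility, with the stated
convention of one mask per subword piece and averaged log-probabilities.

## Typo injection

A word of length n has n+1 splits; the n−1 splits with both sides non-empty
are eligible. The four operators act at the split boundary (insert a random
ASCII letter; delete the first right character; replace it with a different
random letter; swap the first two right characters). Corpus corruption picks
distinct eligible tokens (alphabetic, length ≥ 2), balances the four type
counts to within one, and records every change (position, type, split point,
original, corrupted). Two guarantees are enforced rather than assumed: the
corruption always differs from the original (REPLACE redraws its letter;
TRANSPOSE refuses equal adjacent characters), and a token that admits no
valid transposition swaps its type assignment with another token
deterministically so the quota stays exact. A corrupted token may collide
with a real dictionary word; no filtering is applied, and such collisions are
visible in the records for downstream analysis.

## NER

Schemes: a disease scheme (B/I-Disease, O) and a pathology-record scheme with
B/I labels for ORGAN, LOCATION, OPNAME, and HISTOLOGIC DIAGNOSIS plus
B-TUMOR_SIZE only — size entities are single-token (the leading dimension
number). BIO validation is strict for gold files (errors fail loudly) and
repairs dangling I-X to B-X for predictions. Spans are 0-based,
end-exclusive.

The baseline tagger is a generative sequence model: per-position label scores
are windowed naive-Bayes log-likelihoods of the previous, current, and next
token shapes (numbers normalized to a shape token, words lower-cased) with
add-one smoothing, combined with add-one label-bigram transitions and decoded
by Viterbi restricted to valid BIO moves — predictions are always valid
sequences. The one-token window matters: a number after a comma is a tumor
size, the same number after "×" is not, which a plain emission HMM cannot
distinguish. `predict_marginals` gives the per-token posterior over labels
via forward–backward; rows sum to one. Training is closed-form and therefore
deterministic; the seed parameter is kept for interface stability. The
fine-tuned-transformer path exists behind the same predict contract with the
conventional hyperparameter defaults (learning rate 3e-5, 3 epochs, max
sequence length 178, batch size 16, Adam, softmax activation) and requires
externally supplied weights.

The tumor-size rule accepts "A × B × C cm" with two or three numbers, "×" or
ASCII "x", optional whitespace, and an optional unit; a single number is only
accepted with an explicit "cm" (covering "N cm IN GREATEST DIMENSION"), so
bare counts are never read as sizes. The maximum parsed value is returned.

## Evaluation semantics

Correction: for each aligned token, an injected typo whose output equals the
gold token is a true positive; one left broken or mis-fixed is a false
negative; a mis-fix or a spurious change of a clean token is additionally a
false positive. Hence tp + fn = injected-typo count (the support), precision
penalizes wrong edits, and the report carries a per-error-type breakdown.
NER: entities decoded from gold and prediction match only on exact type and
span (the strictest common convention); micro scores pool entity counts, and
token accuracy is reported alongside. The sweep harness converts a rate to an
absolute balanced-type error count, corrupts the test split with an
independent reproducible substream per rate, and reports entity F1 with and
without correction in rate order.

## Synthetic fixtures

The SPR-like generator fills the template "Organ , Location , OperationName :
HistologicDiagnosis , A × B × C cm" from small tables of clinically plausible
terms (no real records are imitated beyond structure); 10 % of lines use the
"N cm IN GREATEST DIMENSION" variant and 20 % use ASCII "x", so the size
parser's dialect handling is exercised. Dimensions are drawn in 0.3–9.9 cm
with the first number largest, formatted as integers or one decimal. All
entities have length ≤ 3, matching the short-entity profile of real pathology
lines. The prose generator emits weighted template sentences over a closed
vocabulary whose collocations ("right lung", "upper lobe") give the n-gram
backend learnable signal; it deliberately contains confusable pairs
("lung"/"long", "wall"/"well") in which the wrong member is about twice as
frequent, creating the regime where frequency-only correction fails and
context decides.

What a green test on these fixtures does establish: the mechanics and the
direction of every claim (context beats frequency where context
disambiguates; NER degrades with error rate and recovers after correction).
What it does not: absolute performance on real clinical text — the fixtures
have a tiny closed vocabulary, rigid syntax, and no annotation noise, so
absolute F1 values here are far higher than any real-data figure and are not
comparable to published numbers. In particular, the windowed baseline tagger
is more robust to single-token corruption than a real-world tagger, so the
per-rate F1 degradation on fixtures is small (fractions of a point) though
consistently directional.

## Numerical choices and degenerate inputs

Softmax is computed with max-subtraction; candidate probabilities sum to 1
within 1e−9. Empty candidate sets, empty corpora, empty words, out-of-range
λ, and capacity overruns (more requested typos than eligible tokens) raise
typed errors with coordinates where applicable. An unknown token under the
n-gram backend gets the smoothed floor probability, never −∞ or an error.
All randomness flows through a single seeded generator per operation;
repeated runs with the same seed are byte-identical.

## Known limitations

* Real-word (context-sensitive) errors and spacing errors are out of scope:
  only non-word errors are injected and corrected.
* The delete index is rebuilt from the TSV dictionary at load time; no binary
  serialization (at the 2-distance default this is linear in total variant
  count and fast at desk scale, but a PubMed-scale dictionary would want a
  persisted index).
* The n-gram backend's context window is the sentence, but its effective
  conditioning is the (order−1)-token neighborhood on each side — long-range
  context that a transformer MLM would use is invisible to it.
* Tables of printed experimental values from restricted clinical datasets are
  not reproducible here and are not targeted; the harness reproduces metric
  definitions and directions only.
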