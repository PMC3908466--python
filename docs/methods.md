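# Methods

## Task and model

Concept-mention detection is cast as sentence-level sequence labeling over
tokens. A detection *strategy* fixes the set of concept types a model is
responsible for: the **all-types-at-once** strategy trains one model over
the full inventory, the **one-type-** (or a-few-types-) **at-a-time**
strategies first erase all other types' annotations (`project_types`) and
train on the remainder. For k types the external BIO label set has 2k+1
labels; a singleton task has 3.

The tagger is generative and uses only features internal to the text (no
dictionaries, part-of-speech tags or embeddings): every probability in the
system is either a label-bigram probability or a character n-gram language
model probability.

### BMEWO+ representation

Internally each sentence labeling is converted to an enriched BMEWO+
sequence. In-chunk positions: `W_t` single-word chunk, `B_t`/`M_t`/`E_t`
first/middle/last word of a multi-word chunk of type `t`. Outside
positions subdivide by position relative to the neighbouring chunks, and
`B_O`, `E_O`, `W_O` carry a neighbour type:

| position in outside run | label |
|---|---|
| first token, previous chunk of type `t` (or sentence start) | `B_O_t` / `B_O_BOS` |
| last token, next chunk of type `t` (or sentence end) | `E_O_t` / `E_O_EOS` |
| interior token | `M_O` |
| lone token between two chunks | `W_O_<following type>` |
| lone token after the final chunk | `B_O_<preceding type>` |
| lone token before the initial chunk | `E_O_<following type>` |
| only token of a chunkless sentence | `W_O_EOS` |

Two of these rules were genuinely open design choices and are fixed here:
a lone outside token between two chunks is conditioned on the *following*
chunk (mirroring the predictive role of `E_O`), and sentence boundaries
contribute `BOS`/`EOS` pseudo-types so the labeling is total. The
enrichment is invertible: BIO → BMEWO+ → BIO is the identity on valid
input, and the reverse map is total even on ill-formed label sequences
(decoder robustness). The BMEWO+ inventory for k types has 7k+4 labels.

### Emissions: character language models

P(token | label) is a character n-gram LM trained on the token strings
observed under that label, framed with a BEGIN sentinel and closed with an
END event. Conditionals use recursive Witten–Bell interpolation

    P(c | ctx) = λ(ctx)·MLE(c | ctx) + (1 − λ(ctx))·P(c | ctx[1:]),
    λ(ctx)     = N(ctx) / (N(ctx) + D(ctx)),

where N(ctx) is the number of events observed after the context and D(ctx)
the number of distinct continuations. The recursion grounds at the uniform
distribution over alphabet ∪ {UNK, END}, so any string over any alphabet
has finite log probability; characters never seen in training map to UNK.
Witten–Bell was chosen because it is hyperparameter-free and well suited
to the small, morphology-rich vocabularies of token-level models;
alternative smoothing families (e.g. Kneser–Ney) are out of scope. The
distributions provably normalize (tested to 1e-9), and n-gram counts are
not pruned.

The order default is `max_n = 50`, large enough that every token and chunk
string is modelled by its full length; tests use smaller orders for speed
where the order is not the property under test. A label never observed in
training receives the ground (uniform) model over the corpus alphabet —
not over an empty alphabet, which would overestimate short strings.

### Transitions

Label bigrams (with START/STOP framing) are estimated by add-λ-smoothed
MLE with λ = 0.01, with support restricted to *structurally legal*
successors: an explicit rule set derived from the BMEWO+ conventions (e.g.
`B_t` may only be followed by `M_t` or `E_t`; `E_O_t` only by `B_t` or
`W_t`). Illegal transitions keep −∞, so every decodable sequence maps to a
valid chunking. As a safety property the legality rules are tested to
admit every encoder output; bigrams observed in training are additionally
unioned into the legal set. Each row (successors ∪ STOP) normalizes to 1.

### Decoding and rescoring

Exact Viterbi decoding maximizes Σ log trans + Σ log emission; ties break
toward the earlier label in the inventory. N-best decoding keeps the top n
partial hypotheses per label per position (paths are distinct label
sequences by construction); both decoders are tested for exact score and
sequence agreement against brute-force enumeration on small instances.

The n best candidates (default n = 64; the comparison experiments use 8)
are rescored by a second layer of LMs trained on a held-out 20% of the
training sentences: one chunk LM per concept type over chunk surface
strings (tokens joined by single spaces) and one outside LM over outside
segments. Each outside segment is framed by reserved marker characters
encoding the types of the chunks to its left and right (BOS/EOS at
sentence edges), which is how the rescorer, like the enriched HMM labels,
conditions outside text on adjacent types. A candidate's rescored score is
the sum of its chunk-LM and outside-LM log probabilities; the final
ranking uses the rescored score alone (configurable interpolation weight
`alpha` with the HMM score, default 0), with the HMM score breaking ties.
The exact factorization used by the original two-stage chunkers of this
family is not published; this decomposition is this package's documented
interpretation.

The 80/20 split is per document (stratified) and deterministic in the
config seed; corpora with fewer than 5 sentences are rejected rather than
split degenerately.

## Evaluation and experiments

A predicted span counts as correct only with exact boundaries and type.
Precision, recall and F (harmonic mean; 0 when both vanish) are computed
per type. Cross-validation partitions *documents* (never sentences, to
avoid within-document leakage) into k seeded folds of size within ±1, and
reports the arithmetic mean of per-fold P/R/F (macro averaging) — pooled
counts are also shown in report tables but the headline number is the mean
of fold-level ratios. Paired two-tailed t-tests compare per-fold F-scores
between strategies sharing the same folds; if all paired differences are
identical the statistic is degenerate and reported as (0, p=1) for
all-zero differences or (±∞, p=0) otherwise.

`classify_errors` compares a single-type model to the all-types model on
the target type. Over target gold spans correct under the all-types model
and wrong under the single-type model: **boundary error** if some
single-model span overlaps the gold span, else **no detection**. **Type
confusion** counts single-model spans whose boundaries exactly match a
gold span of a different type that the all-types model labeled with its
true type; overlap-without-exact-boundaries with a wrong type counts as a
boundary error, a deliberate sharp edge in an inherently subtle taxonomy.

## Synthetic corpora

Real annotated corpora of this kind are licensed, so experiments run on a
seeded generator that reproduces the *structural* properties the tagger
exploits: documents of tokenized sentences; 3–5 non-overlapping concept
types with relative abundances matching the corpus being emulated (the
3-type clinical preset uses 11.968 : 7.369 : 8.5; the 5-type biology
preset spans a ~30:1 range down to the rarest type), both scaled to 50
documents for desk-scale runs; phrases of 1–4 tokens; and per-type cue
words placed before phrases.

Concept phrases have modifier+head structure: the final token is a head
word carrying a type-specific suffix (e.g. "-oma"/"-itis" vs "-gram"/
"-scopy") and preceding tokens are modifier words with their own
type-specific suffix. This mirrors real mention morphology and is what
makes chunk *boundaries* learnable from characters alone — without it, a
two-token phrase is statistically identical to two adjacent one-token
phrases and no character-based model could separate them.

The **ambiguity scenario** is the controlled setting for the strategy
comparison: two equally frequent types where half of the first type's head
words are *also* used by the second type (directional sharing — the
non-target type borrows target-looking forms, which is the shape of real
type confusion), and cue words (morphologically disjoint between the
types) precede 85% of phrases. A single-type model sees the borrowed
forms sometimes as chunks and sometimes as plain outside text and has no
labels to exploit the other type's cues; the all-types model does, via the
type-conditioned outside labels and rescoring markers. The generator
ledger records vocabularies, shared forms and span counts so tests can
verify the construction (shared fraction ≥ 10% is asserted).

What the generator does *not* emulate: real lexical distributions,
spelling variation, abbreviations and case signals, long-range discourse
structure, and annotation noise. Passing recovery tests therefore shows
the estimator and decoder are correct and that the strategy effect has the
expected direction under controlled ambiguity — not that these F-scores
transfer to real clinical or biology text.

## Problem sizes and numerical choices

Cross-validated experiments in the test suite and acceptance script use:
parameter recovery — the 3-type preset (50 docs, ≈250 spans), 5-fold CV,
n-best 16; strategy comparison — 10 replicates of the ambiguity scenario
(48 docs each), 5-fold CV, n-best 8. These sizes keep a full run in the
tens of seconds on one CPU while leaving the observed effects well clear
of their test thresholds (recovery mean F ≈ 0.87–0.95 against a 0.8
threshold; strategy-gap direction positive in ≥ 8/10 replicates across
multiple disjoint seed sets, mean gap ≈ +0.01 to +0.03).

All scores are natural-log space sums; no probability products are formed.
Empty sentences are skipped when tagging; the empty string has a
well-defined LM probability P(END | BEGIN). Model files are versioned JSON
containers holding the label set, transition tables, all LM counts and the
training configuration; loading a file reproduces tagging output exactly.

## Known limitations

* Byte-level equivalence with the original two-stage chunker
  implementation is not claimed; smoothing details and the rescoring
  factorization are this package's own documented choices.
* Absolute F-scores on the licensed corpora are not reproducible here;
  only arithmetic identities among their published evaluation numbers and
  direction-level findings on synthetic data are.
* The one-type strategy's training cost advantage/disadvantage (wall-clock
  benchmarking) is out of scope.
* `max_n = 50` with unpruned counts is memory-hungry on long chunk
  strings; a context-length cap is available via the LM's `max_n` but no
  count pruning is implemented.
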