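# Methods

## Problem and data model

The package classifies participants of a picture-description interview study
as AD (Alzheimer's dementia) or non-AD from two modalities of one recorded
session per participant:

* a conversational transcript in a minimal CHAT dialect (`*PAR:`/`*INV:`
  speaker tiers; `&`-prefixed filled pauses; `(.)`/`(..)`/`(...)` unfilled
  pauses; `[/]` repetitions; `[//]` retraces; all other inline codes
  stripped, punctuation dropped);
* a per-segment acoustic feature table: the session audio is assumed to have
  been segmented by voice-activity detection, and each segment described by a
  fixed named feature set (emobase, eGeMAPS, ComParE, or a custom table) plus
  its duration in seconds, rows in temporal order.

Cohorts are balanced by class, age and gender, with 54+54 train and 24+24
test participants by default and segment counts around mean 24.86
(sd 12.84) — the structure of the ADReSS-style challenge layout.

## Architectures

All five models share a forward contract: a batch dict of numpy arrays in,
one P(AD) in [0, 1] per participant out; AD is the positive class.

* **A0** (language): two parallel input streams — word embeddings and one-hot
  POS tags — each passed through parallel temporal convolutions (kernel
  sizes 3/4/5, 64 filters each), ReLU, dropout 0.5, then a unidirectional
  LSTM (width 64) read out at the last unmasked step; the two stream vectors
  are concatenated into a dense fusion layer (width 32) and a sigmoid output.
* **A1**: A0 with the LSTMs made bidirectional, additive attention pooling
  (a learned score vector over tanh-projected hidden states, softmax over
  unmasked steps) instead of last-state readout, plus a one-layer dense
  sub-network (width 32) on the 7-value targeted text vector.
* **B0** (speech): a GRU (width 64) over the padded, masked sequence of
  per-segment acoustic feature vectors; because masked steps carry the hidden
  state through unchanged, the state at the final timestep equals the state
  at the last real segment — this "common vector" summarizing the session
  feeds the fusion dense layer and sigmoid output. A bidirectional/attention
  variant exists behind config flags but is not part of the named model.
* **B1**: B0 plus a dense sub-network on the 14 targeted speech features.
* **C**: full A1 and B1 streams are built internally; their latent fusion
  outputs (width 32 each) are concatenated and passed through one more dense
  layer to the sigmoid output.

Layer widths and kernel sizes other than the dropout rate are not fixed by
the model family definition; the defaults above are sized for the ~100-sample
training regime and are all configurable in `ModelConfig`.

The layers run on a small reverse-mode autodiff over numpy written for this
package (float64, deterministic, single-threaded); backpropagation through
every layer type is verified against central finite differences in the test
suite (worst observed deviation ~1e-10 at probe points).

## Targeted features

**Text (7 values, fixed order):** means over participant tokens of four
psycholinguistic norms — age of acquisition (years), concreteness,
familiarity, imageability (1–7-type scales) — a mean sentiment polarity in
[-1, 1], then age (years) and gender (female 0, male 1). Tokens absent from
the norm lexicon are excluded from that norm's mean (coverage is reported);
tokens without a sentiment score contribute 0. Zero lexicon coverage yields
NaN sentinels plus a warning rather than a silent 0.

**Speech (14 values):** six segment-length statistics (mean, median, sample
sd, min, max, count — the conventional completion of the three named
moments); six disfluency/intervention rates — participant words per minute
and interviewer utterances per minute (session minutes = summed segment
durations), plus filled-pause, unfilled-pause, repetition and retrace counts
per participant word (per-word rather than per-minute, which makes them
robust to session length); and DEPID / DEPID-R.

**DEPID.** Each participant utterance is dependency-parsed into
(head, relation, dependent) triples; triples whose relation is in the
proposition-bearing table (nsubj, csubj, obj, iobj, obl, ccomp, xcomp,
advcl, acl, advmod, amod, appos, nmod, nummod, conj — shipped as an editable
text file; determiners, case markers and auxiliaries excluded) are counted
and divided by the participant word count. DEPID-R deduplicates identical
triples across the transcript before counting, so a clause repeated verbatim
contributes once. Parser failures skip the utterance with a warning and
remove its words from the denominator.

The POS tagger, dependency parser and sentiment scorer are pluggable
callables. The defaults are deterministic rule/lexicon backends (closed-class
word lists plus suffix heuristics over the 17-tag universal POS set; a
heuristic clause parser handling simple declaratives; a small polarity
lexicon). They are exact on the templated synthetic transcripts and adequate
smoke-level baselines on real text; for real studies one should plug in a
trained tagger/parser with the same signature.

## Duration-correlation filter

For every acoustic feature, the Pearson correlation R against segment
duration is computed over all segments of the whole cohort pooled
(`fit_scope="all"`, matching the upstream description of the preprocessing;
`"train"` is available as the leakage-safe alternative). Features with
|R| > 0.2 are removed. The absolute value is a deliberate interpretation:
a strong negative duration correlation carries segment-length information
just as a positive one does. Zero-variance features (undefined R) are also
removed, with a warning. The filter is idempotent, and retained counts are
monotone in the threshold.

## Training protocol

AdaGrad, learning rate 0.001, minibatches of 16, up to 200 epochs. Early
stopping monitors validation loss with patience 10 and restores best-epoch
weights. Evaluation is stratified 5-fold cross-validation on the train split
(each fold's held-out part doubles as the early-stopping monitor), reported
as mean ± sd per metric, then a single fit on the complete train split scored
once on the test split. Because early stopping needs a held-out monitored
quantity, the final fit selects its epoch count on a stratified one-fold
validation split first and then retrains from scratch on the full train split
for exactly that many epochs — every train participant contributes to the
final parameters while the stopping point remains data-driven.

Ties at the 0.5 threshold predict AD (closed boundary). Metrics with a zero
denominator are reported as 0 with an explicit flag rather than NaN. ROC
curves are threshold sweeps; AUC is the trapezoidal area, equal to the
Mann–Whitney pair-ordering statistic (verified against a pair-counting
oracle). `confusion_from_recalls` reconstructs confusion counts from
published per-class recalls on balanced test sets (tp = round(recall_AD · n),
tn = round(recall_nonAD · n)), which regenerates published precision/F1/
accuracy values to their printed 4-decimal precision.

All randomness (initialization, minibatch order, dropout, fold assignment,
simulation) flows from explicit integer seeds; repeated runs are
bit-identical.

## Synthetic cohorts

The simulator emulates the *structure* of the study data, not its content:

* segment counts ~ truncated normal(24.86, 12.84, min 3); durations ~
  lognormal(μ=0.9, σ=0.5) — positive and right-skewed like VAD speech chunks;
* 40 acoustic features by default in three blocks: 8 duration-correlated
  (1.0·duration + N(0, 0.1²) noise), 5 class-signal features (AD mean
  shifted by `effect_delta` pooled sds, default 2.0, optionally with a linear
  within-session drift for AD that only a temporal model can exploit), the
  rest white noise;
* transcripts built from templated picture-description clauses over a closed
  vocabulary; the AD class gets elevated per-word filled-pause (0.30 vs
  0.05), unfilled-pause (0.15 vs 0.05), repetition (0.10 vs 0.02) and
  retrace (0.05 vs 0.01) probabilities, more verb-less fragment utterances
  (0.40 vs 0.10, lowering idea density) and more vague-word substitutions
  (0.25 vs 0.05);
* ages and genders are balanced across classes by construction (shared
  deterministic age ladder, alternating gender);
* the embedding table (random unit vectors, dim 16) and the psycholinguistic
  lexicon (uniform over plausible norm ranges) are derived from the same
  seed.

What passing on synthetic cohorts shows: the pipeline is wired correctly
end-to-end, the filter removes what it is constructed to remove and keeps
null features, the Speech-GRU can recover a planted multivariate acoustic
effect at realistic sample sizes, and no information leaks from test labels
(null cohorts score at chance). What it does not show: performance on real
dementia speech — the synthetic vocabulary, clause grammar and feature
distributions are far simpler than real data, and the published real-data
accuracies are not reproducible without the gated dataset.

## Numerical and sizing choices

* float64 throughout; sigmoid/exp clipped for stability; binary
  cross-entropy computed in the logit via softplus.
* `max_segments` 64 (covers mean + 3 sd of the segment-count distribution);
  text `max_len` 512 by default in the encoder, 96–128 in the simulated
  protocols (synthetic transcripts are short).
* Recovery experiments (acceptance script and tests) run B0 at GRU width 32;
  at the simulated feature dimension this halves runtime with no measured
  effect on recovery behavior, and the width is an explicit argument, not a
  change to the model default (64).
* Sample Pearson correlation requires n ≥ 3 and nonzero variance; the filter
  handles the degenerate cases by removal-with-flag.
* Sample sd (ddof=1) for segment-length statistics, defined as 0 for n=1.

## Known limitations

* The default NLP backends are heuristics; DEPID values on real English will
  differ from those produced by a trained parser (the rule table and parser
  are both replaceable).
* The repetition/retrace dialect stores marker kinds and positions but not
  the retraced material itself; round-tripping preserves the data model, not
  the original surface string.
* Model C fuses at the latent level only; word-level multimodal fusion and
  forced-alignment-based pause timing are out of scope.
* LOSO cross-validation is intentionally not implemented; the protocol is
  the stratified 5-fold scheme described above.
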