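# Methods

`promlm` classifies bacterial promoter sequences in two layers — promoter
vs. non-promoter, then strong vs. weak promoter — by treating DNA as text:
sequences become sentences of overlapping k-mer words, words are embedded
with subword-aware vectors at ten n-gram levels, the per-level sequence
vectors are concatenated into one wide representation, and a small 1D
convolutional network makes the call. This note records the model, its
assumptions, the tunable parameters, and the numerical choices that are not
visible from the API.

## Sequence model and tokenization

A record is a string over {A, C, G, T, N}; anything else is rejected rather
than remapped, so corrupt input fails loudly. At n-gram level *n* (word
length *n*, levels 1–10), a sequence of length *L* is tokenized into the
*L − n + 1* maximally overlapping windows at stride 1, on the given strand
only. There is no reverse-complement augmentation, no gapped words and no
canonical collapsing; the ten levels are ten independent tokenizations of
the same molecule.

## Subword embeddings

Each word *w* is represented by the character n-grams (sizes `minn=3` to
`maxn=6`, clipped to the word) of the boundary-wrapped word `<w>`, plus the
whole-word token `<w>` itself, which is distinct from any identical interior
gram. A word scores a context *c* as

    s(w, c) = Σ_{g ∈ G_w} z_g · v_c

with gram vectors `z_g` and context vectors `v_c`. The gram dictionary is
exact — no hash buckets — because the ACGT gram space is tiny; this makes
runs bit-reproducible under a fixed seed, at the cost of fidelity to
large-vocabulary implementations that hash.

Defaults follow the tuned optimum: dimension 100, learning rate 0.1,
context window 5, 100 epochs, softmax loss. Three objectives exist:

- **supervised** (default): a two-class softmax head over the sentence
  representation, where a sentence is the unweighted mean over words of each
  word's gram-mean vector. Updates use **Adagrad** per-parameter steps
  rather than linearly decayed plain SGD: with mean aggregation the gradient
  reaching an individual gram is scaled by 1/(n_words·|G_w|) ≈ 10⁻³–10⁻⁴,
  and plain SGD at lr 0.1 moves nothing on corpora of a few hundred
  sentences. Adagrad keeps the nominal learning rate meaningful at any
  corpus scale and preserves determinism. The trainer records the
  full-corpus cross-entropy after each epoch; because updates are
  per-sentence, this trace can show transient increases of order 10⁻² on
  tiny corpora even though it converges.
- **skipgram** / **cbow**: classic context-prediction objectives with full
  softmax or negative sampling (5 negatives from the unigram^0.75
  distribution). Hierarchical softmax is not implemented and raises a clear
  error; the tuned configuration never uses it.

A **sequence vector** is the mean over words of the word's gram-mean vector
(whole-word token included). Mean — not sum, not length-normalized — keeps
vectors comparable across sequence lengths. Words none of whose grams are
known to the model are skipped; a sentence with no known grams yields a zero
vector with a warning.

## Combined representation

Per-level sequence vectors are block-concatenated in ascending level order:
10 levels × 100 dimensions = 1,000 features, with the block layout recorded
so any level's slice is recoverable exactly. All configured levels must be
present and share one dimension.

## MRMD feature ranking

MRMD implementations vary in their exact distance ensemble, so this package
fixes a fully oracle-checkable instantiation. On z-standardized features:

- relevance `MR_i` = |Pearson correlation of feature *i* with the 0/1 label
  vector| (0 for a constant feature);
- distance `MD_i` = the mean of three inter-feature dissimilarities of
  feature *i* against all others — Euclidean distance, cosine distance, and
  Tanimoto distance (1 − x·y/(|x|²+|y|²−x·y)) — each min-max scaled to [0,1]
  across features before averaging;
- total score = `MR_i + MD_i`, divided by its maximum so the top feature
  scores exactly 1.0. Ties in the descending sort break by ascending feature
  index.

`sweep_select` evaluates top-k cuts (default grid: multiples of 5) by CV
accuracy of a caller-supplied classifier and returns the smallest k
achieving the maximum.

## The convolutional classifier

Architecture, literally the tuned layer list: input (1 × D) → 1D
convolution with 64 filters, kernel 3, stride 1, no padding, linear
activation → explicit ReLU → max pooling size 2, stride 2 → dropout 0.3
(training only, inverted scaling) → flatten → dense layer to 2 units →
softmax. For D = 1000 this is 998 → 499 → 31,936 flattened inputs to the
dense layer. Loss is cross-entropy; the optimizer is adadelta (ρ = 0.95,
ε = 10⁻⁶, step scale 1.0) on mini-batches of 100 for 100 epochs (defaults);
after every update each convolution filter and each dense unit's incoming
weight vector is rescaled to norm ≤ 4 (the max-norm constraint). "64 filter
layers" is read as 64 filters in a single convolution layer. Class calls
are argmax with ties to the positive class.

Numerics: parameters and activations are float32 — the network is
memory-bandwidth bound and a 2-class decision gains nothing from double
precision — with the loss accumulated in float64. The convolution is an
im2col reshape followed by one GEMM; pooling of width 2 uses a single
comparison instead of argmax. Training is seeded and single-threaded;
identical seeds reproduce parameters bit-for-bit. A NaN/inf training loss
aborts with a diagnostic rather than continuing.

The kNN baseline is a Euclidean majority vote (default k = 10, the tuned
value), run under the same CV harness and standardization as the CNN, with
ties to the positive class.

## Evaluation

Confusion counts use the Chou notation (N⁺, N⁻, N⁺⁻ = FP, N⁻⁺ = FN), and
Sens/Spec/Acc/MCC are evaluated in those forms; they are algebraically
identical to the classical TP/TN/FP/FN expressions, and the suite asserts
this on random tables. MCC with a zero denominator is reported as 0 with a
degenerate flag. Metrics are computed as exact fractions and formatted
(percent, rounded half-up) only at report time. AUC is the Mann–Whitney
statistic with ties counted half; the trapezoidal integral of the ROC curve
equals it to machine precision.

Cross-validation is stratified 5-fold (training:validation 4:1),
deterministic under a seed. Two leakage modes exist: by default every
trainable stage — embeddings, the feature scaler, MRMD selection, the
classifier — is fit on the training fold only; in **paper mode** the
per-level embeddings are fit once on the full dataset and shared across
folds — the classical protocol when one language model feeds an entire
cross-validation. The mode is recorded in every run manifest.

The one-sided Wilcoxon signed-rank test (a > b) drops zero differences,
uses midranks for ties, and computes the exact tail for n ≤ 25 by a
convolution over the (doubled) ranks — equivalent to enumerating all 2ⁿ
sign patterns — switching to the tie-corrected, continuity-corrected normal
approximation above. With 10 paired folds the smallest attainable exact
p-value is 1/1024 ≈ 0.00098; smaller printed values cannot arise from this
test at that pairing size.

## Synthetic benchmark

The generator emulates a σ70 promoter screen at desk scale: fixed-length
81 nt uppercase sequences over a uniform background (GC bias is a knob,
default off). Positives carry a degenerate −35-like box (TTGACA at offset
10) and a −10-like box (TATAAT at offset 35), each position corrupted
i.i.d. at the per-position mutation rate — 0.1 for strong promoters, +0.15
for weak ones, so strength is encoded purely by motif fidelity. Negatives
are pure background. Defaults are 400 + 400 sequences, a size at which the
planted signal is cleanly recoverable yet every pipeline stage runs in
minutes on one core.

What the generator does **not** emulate: real base composition, motif
spacing variability, multiple sigma-factor classes, or any dependence
structure among promoter positions. Passing the planted-signal checks
therefore demonstrates that the pipeline recovers a localized degenerate
motif signal end-to-end and that its null behaves (label permutation drives
AUC to 0.5); it does not certify performance on curated genomic data.

## Problem sizes used by the test suite and acceptance script

The heavy end-to-end checks run on the generator defaults (400 + 400 × 81
nt) with 10 embedding epochs per level and 15 CNN epochs — on this
separable benchmark both training curves plateau well before the tuned
100/100, which remain the package defaults for real data. The combined
representation is compared against single levels over 2 CV repeats; the
label-permutation null uses one repeat.

## Known limitations

- The supervised objective trains a linear head over an averaged bag
  representation; its own CV AUC saturates near 0.87–0.9 on small corpora.
  The downstream classifier on extracted vectors is the stronger (and
  default) path.
- Hierarchical softmax is absent (see above).
- Exact subword dictionaries grow with the word-level vocabulary; at level
  10 on large corpora memory scales with the number of distinct 10-mers.
- No independent test-set protocol is provided: evaluation is CV-only, by
  design.
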