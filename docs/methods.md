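# Methods

This document is the scientific account of what `lattice123` computes: the
feature transform, the selection/classification/fusion pipeline, the synthetic
data generator, and the numerical and statistical properties a user should
know before interpreting results.

## 1. The lattice and its walking paths

The transform is built on a fixed directed acyclic graph of 19 vertices
arranged in 9 tiers of sizes (1, 2, 3, 3, 3, 3, 2, 1, 1), numbered 1..19 tier
by tier. All 28 edges connect adjacent tiers, produced by three local rules
(with 1-based positions inside each tier):

* expanding tier (size a → a+1): parent i feeds children i and i+1;
* equal-size tiers: parent i feeds children i and i+1, truncated at the tier
  edge;
* contracting tier (size a → a−1): child j is fed by parents j and j+1.

Vertex 1 is the unique source and vertex 19 the unique sink, so every
source-to-sink traversal visits exactly one vertex per tier: 9 vertices,
8 edges. A *walking path* is the greedy traversal that, at each tier, steps
to the child whose assigned probability is smallest (`minimum` walk) or
largest (`maximum` walk); ties go to the lower-numbered child, and the final
step is forced to the sink. Alternative topologies can be supplied through a
plain-text config (`lattice.load_topology`), subject to the same
single-source/single-sink, adjacent-tier validation.

## 2. The transform: signal → six 256-bin histograms

For a one-dimensional signal `x` of length `n ≥ 19`:

1. **Normalization.** `x` is min-max normalized to integers 1..100 via
   `ceil((x − min) / (max − min) · 99) + 1`; a constant signal maps to all 1s.
2. **Probability table.** The empirical probability of each normalized value
   1..100 is tabulated over the whole signal.
3. **Blocks.** The signal is scanned with overlapping 19-sample blocks
   (stride 1, `n − 18` blocks). Block sample j populates lattice vertex j and
   carries the global probability of its normalized value.
4. **Walks.** Each block generates one minimum and one maximum walking path.
5. **Kernels.** Along a path's 8 edges, three binary comparison kernels are
   applied to the *raw* (unnormalized) sample values a (earlier vertex) and b
   (later vertex):
   * signum: bit = 1 iff a − b ≥ 0;
   * upper ternary: bit = 1 iff a − b > tr;
   * lower ternary: bit = 1 iff a − b < −tr;
   where the threshold `tr` is half the population standard deviation of the
   whole source signal.
6. **Codes.** The 8 bits form a byte with the first-traversed edge as the
   least significant bit, giving a code 0..255 per block per (walk, kernel)
   combination.
7. **Histograms.** Each of the six code streams is histogrammed into 256
   bins. Category numbering is frozen: 1 = (min, signum), 2 = (max, signum),
   3 = (min, upper), 4 = (min, lower), 5 = (max, upper), 6 = (max, lower).

Conservation laws used throughout the test suite: every histogram sums to
`n − 18`, and every walk is a valid 9-vertex lattice path.

Two implementations exist — a vectorized NumPy path and a compiled
(numba) per-block core — and are kept bit-identical; the test suite also
checks both against an independent straight-line loop reference.

## 3. Multilevel features

Each epoch is decomposed by four iterated single-level db4 discrete wavelet
transforms with half-point symmetric boundary handling, keeping only the
approximation (low-pass) coefficients; each level has length `(n + 7) // 2`
of its input. The transform is applied to the raw epoch and to the four
subbands, and for each category the five 256-bin histograms are concatenated
(raw, L1, L2, L3, L4) into one 1280-dimensional feature vector — six vectors
per epoch per channel. The minimum epoch length for usable level-4 subbands
is 199 samples.

## 4. Selection, classification and fusion

Per channel, each of the six 1280-column feature matrices goes through:

1. **NCA ranking.** A per-feature (diagonal) neighborhood component analysis
   weight is learned by maximizing the regularized leave-one-out NCA
   objective with L1 neighbor distances (regularization 1/n, all-ones
   initialization, L-BFGS capped at 15 iterations; columns are z-scored for
   weight learning only). Columns are ranked by descending weight.
2. **Iterative selection.** Nested ranking prefixes of sizes 100..512 are
   each scored by 1-nearest-neighbor (city-block) accuracy under seeded
   stratified 10-fold cross-validation; the most accurate prefix wins, ties
   going to the smallest. The fold assignment is shared across all six
   categories of a channel (and across channels), so prediction vectors are
   fold-aligned.
3. **Voting.** The six out-of-fold prediction vectors are fused by iterative
   hard majority voting: vectors are sorted by accuracy (descending, stable),
   and for r = 3..6 the element-wise mode of the top r vectors forms a voted
   vector (ties resolve to the tied label predicted by the most accurate
   member). Six inputs yield four voted vectors.
4. **Greedy choice.** The most accurate of the 10 candidates (6 classifier +
   4 voted) becomes the channel's prediction vector.

At the collection level the channel winners are fused the same way: with 59
channels, voting over r = 3..59 yields 57 voted vectors, and the greedy step
picks the best of 116 candidates. By construction the final accuracy is at
least the best single-category and best single-channel accuracy (greedy
dominance).

The L-BFGS cap of 15 iterations was fixed after verifying that planted
informative features are recovered identically at 15 and 30 iterations and
that the ranking stabilizes early; it is a runtime choice, not a tuning knob.

## 5. Metrics

Results are reported as a 2×2 confusion matrix (rows = truth, columns =
predicted) plus class-wise sensitivity, specificity, precision and F1 in
percent, their unweighted (macro) means, accuracy, and the geometric mean
`sqrt(sens_A · sens_B)` — in a binary problem the specificity of one class is
the sensitivity of the other, so this is the imbalance-robust headline
metric. Displayed tables round half-up to two decimals.

## 6. Synthetic data generator

`generate_synthetic` produces seeded multichannel two-class epoch
collections. Each epoch is a sum of band-limited Gaussian noise components
(delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz), each
synthesized in the frequency domain and standardized so its time-domain
variance equals the configured band power, plus a white noise floor
(variance 0.25). Defaults: 59 channels, 78 + 22 epochs (≈3.5:1 imbalance),
3750 samples at 250 Hz. The impaired-class profile follows the EEG
"slowing" convention — elevated theta (4.0 vs 1.0) and suppressed alpha
(0.5 vs 2.0) relative to controls — making the two classes strongly
separated spectrally. Setting both profiles equal yields null data with no
class signal. Channels are independent realizations of the class profile;
epochs are shuffled within the seeded stream.

## 7. Selection optimism on null data

The pipeline is *self-organized*: prefix selection, voting and the greedy
choices are all scored against the true labels of the same cross-validated
predictions they choose among. This maximization over many
label-dependent candidates (413 prefix sizes × 6 categories × channels,
then 116 fused candidates) is performed outside any nested validation
loop, so the reported cross-validation accuracy is an optimistically biased
estimate of generalization. On null data (identical class profiles) at desk
scale (60 epochs) the composed optimism is large: a single category's
selected-prefix accuracy already exceeds the class prior by ~10 points, and
the fused result can reach 100% despite the absence of any class signal.
The effect shrinks with sample size but is inherent to the architecture.
Consequently: treat the pipeline's headline accuracy as a model-selection
score, not an unbiased error estimate; unbiased estimates require an outer
held-out set or nested cross-validation, which this package deliberately
does not silently substitute. The acceptance suite includes a null-profile
calibration check written against the ideal (accuracy ≈ prior); it fails by
design at this sample size and documents the measured optimism.

## 8. Study sizes and runtime choices

End-to-end synthetic studies in the test suite and acceptance script use 60
epochs (47 + 13, preserving the default imbalance) per 59-channel run, with
the full 100..512 selection sweep — about 50–70 s per run on one CPU. These
sizes are this package's own desk-scale choices to fit a CI budget; the
generator defaults (100 epochs) and all pipeline parameters are unchanged.
The planted-feature recovery study uses n = 150 observations with 12
informative columns (2σ class shift) among 108 noise columns, sweeping
prefixes 12..60.

## 9. Limitations

* Binary classification only; metrics enforce exactly two truth classes.
* No EEG preprocessing (filtering, artifact rejection, re-referencing) —
  input is segmented raw signal.
* EDF ingestion requires the optional `mne` dependency; delimited text
  matrices are supported natively.
* The cross-validated accuracies are selection-biased (section 7).
* F1, geometric mean and macro averages are always recomputed from the
  package's own confusion matrix, never accepted from external tables.
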