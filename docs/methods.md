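# Methods

`misinfonet` re-implements, as a tested and reusable pipeline, a study
protocol for classifying short health-related social-media texts into
*trustworthy information* versus *misinformation*: harmonize labels from
heterogeneous fact-checking sources, clean tweet-style text, embed each
document as a fixed-shape matrix, rebalance the scarce trustworthy class by
cosine-similarity injection against a small verified seed sample, train a
four-pathway 2-D convolutional classifier alongside six comparison models,
and evaluate with confusion-matrix metrics, per-class reports, ROC/AUC and
stratified k-fold cross-validation. The original tweet corpus is not
redistributable, so a synthetic corpus generator supplies data with the
statistical structure the protocol assumes; readers for the real corpus
formats are provided.

## Text model and preprocessing

Cleaning applies a fixed cascade: strip URLs and @-mentions, lowercase,
replace punctuation with spaces (so hyphenations and hashtags keep their
word bodies: `covid-19` → `covid`), delete digit characters in place
(Unicode-aware), split on whitespace, drop stop words and single-character
tokens. The cascade is idempotent and every surviving token is a lowercase
multi-character word. Duplicates are removed on *cleaned* text, first
occurrence wins. The stop-word list is a standard English list shipped as a
plain-text data file and overridable per run.

Each document is represented to the convolutional model as a
`max_tokens x dimension` matrix, by default **100 x 100**: row *i* holds
the 100-dimensional vector of token *i*, documents longer than 100 tokens
are truncated, shorter ones zero-padded. Out-of-vocabulary tokens map to
the zero vector — zeros are the neutral element for convolution. Vectors
come either from a GloVe/word2vec plain-text file or from the default
*hashing provider*, which maps each word through a keyed BLAKE2 digest to a
seeded unit-norm Gaussian vector. The hash provider needs no download, is
bit-reproducible across machines, and — because the downstream tasks here
depend on token identity rather than distributional semantics — supports
every test at full strength. What it does *not* emulate is semantic
neighborhood structure: with hashed vectors, two synonyms are as distant as
two unrelated words, so results on synthetic data say nothing about how
much pre-trained embeddings would help on real language.

## Minority-class augmentation by cosine similarity

The trustworthy class is typically the scarce one. The augmentation step
scores each unlabeled candidate document by its **maximum TF-IDF cosine
similarity to a verified-trustworthy seed set** and injects every candidate
scoring strictly above a calibrated threshold into the corpus with the
trustworthy label and an `injected` provenance flag. Design choices:

- **Representation.** Smoothed TF-IDF over cleaned unigrams. The sparse
  term-weight representation is the standard choice for short-text
  similarity; the 100x100 embedding matrices belong to the network, not to
  this step. A mean-over-seeds aggregation is selectable by config
  (`aggregation="mean"`); the default maximum implements a
  nearest-trustworthy-example criterion.
- **Threshold calibration.** For each candidate threshold in the default
  grid {0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4}, the verified sample (by
  default 180 trustworthy + 70 misinformation documents) is scored and the
  documents strictly above the threshold are tallied by verified label;
  precision is the trustworthy fraction. The chosen threshold maximizes
  exact (unrounded) precision; ties break toward the threshold with more
  verified-trustworthy documents above it, then toward the smaller
  threshold. Both secondary rules maximize injection at equal purity. A
  `min_injected` floor and a fixed-threshold override are exposed: expert
  reviewers may prefer a higher threshold than the argmax when the
  precision profile is flat but the contamination risk differs — with the
  reference tallies this pipeline mirrors, exact precision selects 0.2
  (145/193 = 0.7513) while the original analysts selected 0.3 after expert
  review; `CosineSimilarityAugmenter(threshold=0.3)` reproduces that
  choice.
- **Strictness.** "Over the threshold" is strict inequality throughout.
- **Conservation.** Injection never alters, relabels or removes existing
  documents; candidates whose id already exists are skipped and logged.

## The convolutional classifier

The network reads the single-channel 100x100 token-by-dimension plane
through **four parallel pathways** with kernels 12x12, 2x2 (patterns
spanning token rows — inter-sentence), 11x2 and 1x3 (patterns within and
along rows — intra-sentence). Each pathway stacks **three same-padded
stride-1 convolutions**, applies **dropout (rate 0.5) before its single
ReLU** — placing dropout ahead of the rectification is the deliberate
overfitting countermeasure — then 2x2 max pooling. The intra pair and
inter pair are concatenated, joined, flattened, passed through a 128-unit
ReLU dense layer and a single sigmoid output giving P(misinformation).
Training: Adam, binary cross-entropy on logits, learning rate 1e-4, batch
size 128, exactly 5 epochs. All randomness (initialization, shuffling,
dropout) derives from one seed.

Open geometry settings and their defaults: **4 filters per convolution**
(the headline quality bar is reached with large margin at this width, and
it keeps a 2,000-document run in minutes on one CPU — see *Problem sizes*),
same-padding, stride 1, 2x2 pooling, Glorot-uniform initialization. All are
config-exposed.

The numerical backend is an in-package reverse-mode autodiff engine over
numpy (float32). Convolutions execute through two interchangeable paths: a
tap-loop GEMM path for small kernels and an FFT path (cyclic convolution of
zero-padded operands; adjoints are cyclic correlations) for large ones.
Both paths agree to float tolerance and are gradient-checked against
central differences. Batches of 128 are processed as accumulated
micro-batches of 32 — mathematically identical updates, bounded memory.

## Comparison models

Decision tree, random forest and SVM use the scikit-learn defaults
(recorded in each run's resolved config) on the same TF-IDF features as
the augmentation step. The stacking ensemble trains those three as base
learners and a logistic meta-classifier on their out-of-fold predicted
probabilities (5-fold) — the standard leak-free construction. GRU and LSTM
classifiers consume token-index sequences padded/truncated to the same
100-token budget, with a trainable embedding (frozen zero padding row),
one or two recurrent layers of 16-128 cells, and the same optimizer/batch
settings as the convolutional model; dropout and L1/L2 penalties are
exposed because recurrent models are the ones prone to overfitting here.
The overfitting detector flags a history when the train-validation
accuracy gap exceeds 0.15 for two consecutive epochs, or when validation
loss rises while training loss falls for two consecutive epochs; both
constants are arguments.

## Evaluation

Accuracy, precision, recall and F1 come from the standard confusion-matrix
formulas; **zero-denominator metrics are reported as absent, never as 0**,
so fold averages stay honest. ROC AUC is the Mann-Whitney concordance
probability with ties half-weighted; on small sets it is tested against an
all-pairs brute-force count. Per-class tables treat each class as positive
in turn (one-vs-rest); per-class "accuracy" is the one-vs-rest accuracy —
an interpretation, documented as such. Cross-validation is stratified
k-fold (default k=5) with per-fold retraining and unweighted averaging of
fold metrics. Reported rounding follows the tables the package mirrors:
two decimals on percentage scales, three for AUC.

## Synthetic data: what it does and does not establish

The generator emulates the features the pipeline depends on: short
documents (8-30 tokens, hard cap 40), two topic vocabularies of 300 words
plus 200 shared background words with mildly Zipf-skewed frequencies,
exact class allocation (`round(n * minority_fraction)` trustworthy
documents — no binomial jitter in count-based tests), exact label-noise
flipping with ground truth retained, and optional noise switches
(duplicates, numeric tokens, punctuation bursts) that are off by default
and exist to exercise individual cleaning rules. `topic_purity` is the
probability a token comes from the class vocabulary; of the remaining
background mass, `cross_topic_rate` (default 0.2) is drawn from the *other*
class's vocabulary. That leakage exists because real misinformation quotes
trustworthy wording: it gives the two classes overlapping similarity
distributions, so threshold calibration sees a declining false-positive
profile across the grid rather than a degenerate all-or-nothing split. The
verified-seed generator emulates a small fact-checked sample (default 250 =
180 + 70) plus an unlabeled candidate pool (default 1,500, two thirds truly
trustworthy) carrying hidden ground truth for recovery tests.

Synthetic corpora are far cleaner than real tweets: vocabulary is closed,
topics are axis-aligned, noise is optional, and there is no semantic
structure. Passing the suite therefore establishes that the *pipeline
machinery* is correct (calibration tallies, injection rules, training
mechanics, metric formulas), not that any accuracy level transfers to real
social-media data.

## The end-to-end desk run

`misinfonet.pipeline.desk_run` chains
simulate → calibrate → augment → train → evaluate under the default study
conditions: 2,000 documents, minority fraction 0.15, topic purity 0.9,
fixed seed. Because augmentation rebalances the data used for training
*and* testing, the stratified train/test split (80/20) is taken after
injection, and the majority-class baseline refers to that test split; with
an 85/15 split before augmentation no classifier could beat the majority
baseline by 20 points, so the post-augmentation split is the only reading
under which that quality bar is meaningful. An unaugmented control arm
(same generator, same split protocol, no injection) isolates what the
injection buys; under the default conditions the control collapses to
majority-class prediction (minority recall 0) while the augmented arm
recovers minority recall above 0.95.

## Problem sizes and numerical choices

Desk-scale sizes were chosen so the whole protocol runs on a single CPU
core in minutes: with 4 filters per convolution the augmented arm
(~2,900 documents after injection, 5 epochs) trains in ~5 minutes and the
control in ~3. Unit tests exercise the same code paths on reduced
geometries (20x16 planes, 2 filters, short sequences). Other numerical
choices: float32 weights and activations; FFT sizes padded to the next
fast length; BCE computed stably from logits via softplus; Adam with the
standard bias correction; inverted dropout. Degenerate inputs are defined
behavior: empty documents clean to the empty string, all-zero matrices
classify without error, empty TF-IDF vectors are rejected at the cosine
step with a clear message.

## Known limitations

- The hashing embedder carries no semantics; pre-trained vectors are
  supported but not bundled.
- The TF-IDF vocabulary is fitted on corpus + pool + seeds jointly; a
  deployment that streams new candidates would need an incremental or
  frozen vocabulary.
- Recurrent baselines read the last hidden state after right-padding;
  masked pooling would be better for highly variable lengths.
- Per-class "accuracy" follows the one-vs-rest interpretation; other
  conventions exist and are not derivable from the mirrored tables.
- The single-channel plane treats the document as flat token rows; no
  sentence segmentation is attempted.
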