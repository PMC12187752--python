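# Methods

## Problem setting and data model

The classifier decides whether the central lysine of a fixed-length peptide
window is crotonylated. Windows are 29 residues (`window_length`, odd so the
K sits exactly at position 14, 0-based). Windows cut from full proteins near
a terminus are padded with `-`, which is a first-class vocabulary token
rather than an overloaded amino-acid letter; non-canonical residues
(B, J, O, U, Z) are collapsed to the unknown token `X` at load time, keeping
the vocabulary at 22 tokens. Labels are carried by file membership
(positive/negative FASTA pair). `source_position` is 1-based (the convention
in site tables); internal indices are 0-based.

## Encoding

Windows are tokenized into overlapping k-mers (default k = 1, stride 1, so
29 tokens per window). The token embedding is a skip-gram model with
negative sampling: each (center, context) pair within a context window of 5
contributes a logistic update against 5 noise tokens drawn from the unigram
distribution raised to 3/4. Updates are applied in mini-batches of at most
4,096 pairs with the mean gradient and a linearly decaying step size
(initial 0.3, floor 10%), for 25 epochs by default; with a 22-token
vocabulary this converges quickly and is bit-reproducible for a fixed seed.
CBOW vs. skip-gram, the context width and the epoch count are genuinely
open choices for this encoder; skip-gram was chosen as the canonical
word2vec reading and all three are exposed as parameters.

The embedding is always fitted on the training split only (per fold during
cross-validation) so that evaluation windows never influence the encoder.
`embed_encode` is definitionally the embedding matrix times the one-hot
encoding; the package keeps both paths and tests their exact equality.

## Architecture

Input is an (N, 80, 29) batch: 80 embedding channels over 29 positions.
Convolutions are 1-D along the position axis — the natural choice for
sequence feature maps, and consistent with attention that weights *feature*
channels. There is no initial convolution: the encoded matrix enters the
first dense block directly.

* **Dense block.** `layers_per_block` composite layers, each
  BN → ReLU → Conv(kernel 3, stride 1, same padding, `growth_rate` = 32
  output channels); layer *l* consumes the channel-concatenation of the
  block input and all previous layer outputs, and the block emits the full
  concatenation. Entering with C channels it exits with
  C + layers_per_block × growth_rate.
* **Transition.** BN → 1×1 conv to ⌈compression · C⌉ channels (compression
  0.5) → average pooling (window 2, stride 2), flooring the length. The
  batch-normalization layer between a block and its transition is realized
  as the single leading BN of the transition composite — one BN, not two.
* **Attention placement.** After the last dense block only, with no
  transition after that block (blocks are separated by n_blocks − 1
  transitions). This keeps 3 positions under attention with the default
  geometry 29 → 14 → 7 → 3.
* **RCAM.** The bottleneck FNN (C → C/r → C, r = 8, ReLU inside) is shared
  between the average- and max-pooled paths. The residual term is
  σ(AvgPool F + MaxPool F) applied to the *raw* pooled statistics with no
  rescaling — the pooled magnitudes are unbounded, so this sigmoid can
  saturate; that behavior is intentional and kept as specified by the
  mechanism's definition. The CAM ablation simply omits the residual term.
* **Head.** Flatten → one hidden FC layer (64, ReLU, dropout 0.5) →
  2-unit softmax. Head widths, kernel size, growth rate, compression and
  dropout have no canonical published values for this architecture; the
  defaults here are standard DenseNet-style settings scaled to the small
  input, and every one is a `ModelConfig` field.

The number of dense blocks (4) and conv layers per block (2) are the
defaults because they win the accuracy/MCC grid search that
`grid_search` reproduces on arbitrary data.

## Training

2-class cross-entropy on softmax outputs; Adam (lr 1e-3) with batch 64,
early stopping on the loss of a stratified 10% validation split (patience
10), best-epoch weights restored. None of these values are canonical for
the architecture; they are robust defaults and all sit in `TrainConfig`.
Batches that would reach batch normalization with fewer than 2 samples are
skipped (BN batch statistics are undefined there). A non-finite loss aborts
with a diagnostic rather than training on. With a fixed seed the entire
run — init, shuffling, dropout masks, fold assignment — is bit-reproducible
on a fixed device.

Folds are stratified (per-class round-robin after a seeded shuffle): fold
sizes differ by at most one and per-fold class counts are within one of the
fair share. Grid search marks combinations whose transitions would shrink
the length below one position as infeasible rows instead of failing, and
breaks ties by Acc, then MCC, then fewer parameters.

## Metrics

Sn, Sp, Acc and MCC come from the confusion matrix with "predict positive
iff score ≥ threshold" (ties at the threshold are positive calls; threshold
default 0.5). MCC returns 0 when its denominator vanishes. The ROC is a
threshold sweep over the unique scores and AUC its trapezoidal area, which
under this construction equals the Mann–Whitney statistic
P(score⁺ > score⁻) + ½ P(tie); the test suite pins this equivalence to
1e-9 against an O(n²) pairwise oracle and cross-checks against
scikit-learn.

## Synthetic data generator

The generator emulates the *shape* of curated Kcr benchmarks: fixed-length
K-centered windows, balanced classes, file-pair layout. Positives carry a
categorical mixture at motif offsets ±1, ±2: with probability
`motif_strength` the position's consensus residue, otherwise a background
draw. Negatives are pure background. Defaults: strength 0.9, uniform
background (a natural-frequency preset, `NATURAL_AA_FREQS`, is provided),
1,000 windows per class. Strength 0.9 at four offsets puts the closed-form
Bayes accuracy at 0.9914 — high enough that a correct implementation must
learn it almost perfectly, low enough that beating it signals leakage.

Because positions are independent and non-motif positions are identically
distributed in both classes, the likelihood ratio depends only on the motif
positions; `expected_separability` convolves the per-position
log-likelihood-ratio distributions exactly (dictionary convolution with
rounded keys) and returns 0.5 Σ max(P, Q), ties counting half. Trained
models are checked both to approach this ceiling and not to exceed it
beyond binomial noise.

What the generator does **not** emulate: positional correlations,
evolutionary conservation, homology between windows, class imbalance, and
the long-tailed residue composition of real proteomes. Passing the
synthetic end-to-end tests therefore demonstrates that the pipeline can
extract a planted, information-theoretically quantified signal — not that
it attains any particular accuracy on biological benchmarks, which depend
on the external data deposit.

## Numerical choices

* The network is implemented directly in NumPy (im2col convolutions,
  hand-derived backward passes); gradients were verified against central
  finite differences (median relative error ~1e-9 on a small
  configuration).
* BN eps 1e-5, running-statistics momentum 0.1; evaluation mode uses
  running statistics and disables dropout, making inference deterministic.
* Max-pool gradients route to the first argmax on ties; average-pool
  flooring drops a trailing odd position.
* Softmax is computed with max-shift; sigmoids are evaluated in the
  numerically stable branch form.
* Sn/Sp are NaN when their class is absent (the report still carries the
  other metrics); an all-zero confusion matrix is an error.

## Problem sizes used in the shipped checks

Unit tests run on tiny tensors and scaled-down architectures (8–16
channels); the end-to-end checks train the *default* architecture on 2,000
synthetic windows and evaluate on 2,000 more, with the embedding trained
for 5 epochs there — enough for the 22-token vocabulary. The acceptance
script uses the same sizes. These sizes were chosen as the smallest at
which the Bayes ceiling, the chance-level control band (±0.05 around 0.5 at
n = 2,000) and the learning claims are statistically meaningful.

## Known limitations

* No GPU path and no learning-rate schedules; training the full published
  benchmark (~14k windows) takes correspondingly longer than a framework
  implementation, though it remains feasible.
* The alternative attention modules (SE, ECA, CBAM, DA) and backbone
  families compared in the literature are out of scope; only the
  none/CAM/RCAM axis is implemented.
* AAindex and protein-language-model encoders are out of scope; the
  tokenizer supports k > 1 but no k-mer comparison harness is shipped.
* Checkpoints store raw float64 arrays (`.npz` + JSON config sidecar); they
  are not interchangeable with other implementations' weight formats.
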