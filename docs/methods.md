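# Methods

This note documents the models and procedures the package implements,
the tunable parameters and their defaults, what the synthetic data
generator does and does not emulate, and the numerical and design
choices made where the design was genuinely open.

## Data model

A dataset is `MtscDataset`: values (n × m × l), integer labels 0…c−1
(class names mapped in sorted lexicographic order, fixed across splits),
and a binary mask (1 = observed).  Variable-length cases are padded to
the longest case; padded positions and interior missing observations
(NaN or `?` in `.ts` files) get mask 0.  After `finalize`, every masked
position holds the fill value 0 — on z-normalized channels this is the
channel mean, which is inert under convolution.  Channel statistics for
z-normalization are computed over observed positions only, with a std
floor of 1e−8 for constant channels; test splits reuse training
statistics.  The mask is carried through the pipeline and exposed to
callers, but the default encoder does not consume it (there is no
masked-convolution architecture here); `use_mask_channels=True`
concatenates the mask as m extra input channels instead.

## Architecture

The encoder is the canonical time-series ResNet: three residual blocks,
each three conv–batchnorm–ReLU layers with kernel sizes (8, 5, 3),
stride 1 and same-padding throughout (even kernels pad one extra
position on the left), filters (64, 128, 128) by default, an identity
shortcut (1×1 conv + BN when channel counts change), and global average
pooling over time.  Length preservation matters: the final feature maps
align one-to-one with input time steps, which is what makes Grad-CAM
attribution need no upsampling.  The projection head is
linear(128)–ReLU–linear(D=64) followed by L2 normalization; the
classifier is linear(128)–ReLU–linear(c) with softmax.  One weight set
serves both the source and target branches (a Siamese pair with shared
weights, no momentum/EMA target); gradients flow through both views,
while memory-bank entries are stored detached so historical activations
are never back-propagated.

Head widths and embedding dimension are package choices (the
architecture family fixes the encoder, not the head sizes); all are
configurable through `EncoderConfig`.

The network runs on a small reverse-mode autodiff core written on numpy
(`supcon_tsc.autodiff`): broadcasting arithmetic, matmul, a stride-1
same-padded conv1d implemented as K shifted batched matmuls, a fused
batch-normalization node, ReLU and reductions, all in float64.  Every
operator's gradient is finite-difference checked in the test suite.

## Losses

Instance-level: the comparison set A(k) for source-view anchor k is all
N target-view embeddings of the batch, and the positive set P(k) is the
same-label targets **including the anchor's own target view** — so
|P(k)| ≥ 1 and the loss is defined even for a label that appears once in
the batch (a singleton anchor contributes the self-consistency term
only; for N = 1 the loss is exactly 0).  Cluster-level: the comparison
set is the whole memory bank; anchors whose label has no bank entry
contribute 0 and are counted in a `skipped` diagnostic (an empty bank
gives total 0, all anchors skipped).  Both softmaxes subtract the
per-anchor maximum logit before exponentiation.

Cluster centers are plain per-label arithmetic means of the target
embeddings, **not** re-normalized to the sphere — the mean of unit
vectors has norm < 1, and re-normalizing would silently change the
effective temperature of the cluster term.  `renormalize_centers=True`
opts in for users who want unit prototypes.

The combined objective sums per-anchor losses (reduction `sum`;
`mean` is available for batch-size robustness — the learning rate
absorbs the scale either way).  The warm-up gate is α = 0 for
epoch ≤ N_w and 1 afterwards, with epochs 1-based.  Duplicate labels
accumulating across bank batches are kept: the bank is a history, and
deduplication would reweight recent batches unpredictably.

Default temperature τ = 0.1 — a standard value for normalized-embedding
contrastive objectives; exposed as `loss.tau`/`TrainConfig.tau`.

## Memory bank

`ClusterMemoryBank` retains at most `capacity_batches` batch snapshots
(default 16), each holding one center per label present in that batch,
so at most N_buffer × N_l entries.  Eviction is strictly
oldest-batch-first — the bank's N_buffer × N_l × D shape implies a ring
over batches, and FIFO is the only policy consistent with that.  An
empty update is a no-op.  Stored centers are historical: they are not
refreshed by the current encoder before use, so early after warm-up the
bank deliberately mixes slightly stale prototypes with current anchors.
The bank resets at the start of each training run and is excluded from
checkpoints — stale embeddings from an unrelated encoder are
meaningless.

## Training

Stage 1 (per batch): draw strong/weak views (additive Gaussian jitter,
i.i.d. over observed entries; defaults σ_strong = 0.5, σ_weak = 0.05 on
z-normalized channels — an order of magnitude apart to make
"high-variance" vs "low-variance" concrete; masked entries are never
jittered), encode and project both views, compute per-label centers of
the detached target embeddings, update the bank, then take an Adam step
(lr 1e−3, β = (0.9, 0.999)) on instance + gated cluster loss.  The last
incomplete batch is dropped in stage 1 (contrastive losses degenerate at
tiny N) and kept in stage 2.  Warm-up defaults to ceil(0.2 · epochs):
the bank should be populated by a partially-trained encoder before its
term activates, but well before training ends.  No scheduler, no early
stopping: a fixed epoch count keeps runs exactly reproducible.

Stage 2 freezes the encoder bit-for-bit: pooled features are computed
once in eval mode (batch-norm running statistics) and only the
classifier MLP is trained, full-batch, with cross-entropy.  The
ablation baseline (`with_supcon=False`) trains a fresh encoder +
classifier jointly with cross-entropy for the same number of epochs as
stage 1, and never touches the projection head or the bank.

Stratified k-fold ensembling (default k = 5) trains one two-stage model
per fold and averages softmax **outputs** (not logits) at prediction
time; argmax ties break toward the lowest class id.  One user seed fans
out through a splitmix-style hash into independent streams for weight
init, shuffling, augmentation and fold assignment, so runs are
reproducible and streams decorrelated.

## Grad-CAM

The class score is the pre-softmax logit — attribution is then invariant
to adding a constant to all logits and does not vanish when the softmax
saturates.  Weights average the logit's gradient over the l temporal
units of the final conv feature maps (Z = l; the encoder preserves
length, so there is no pooling ambiguity); the map is the ReLU-clamped
weighted sum, length l, non-negative.  Attribution runs through the
stage-2 path (encoder + classifier).  Channel-wise attribution is out of
scope: relevance is over time only.

## Comparison statistics

`pairwise_wins` counts wins/ties/losses of one method over another
across datasets, excluding rows with a missing cell in either column;
the conventional "outperforms on k of n" headline is wins + ties.  The
Friedman test uses mid-ranks (rank 1 = best) with tie correction
(delegated to scipy), dropping and reporting incomplete rows; all-tied
tables return statistic 0, p = 1.  Pairwise two-sided Wilcoxon
signed-rank tests (zero differences dropped by default, Pratt variant
configurable) are Holm step-down corrected at α = 0.05, and cliques of
mutually non-distinguished methods are maximal groups contiguous in
mean-rank order with no rejected internal pair.  The package ships the
29-dataset × 9-method benchmark accuracy table and the 29-row ablation
table as CSV fixtures; the win/tie counts recomputed from them are
exact.  Reproducing the source benchmark's omnibus p-value and average
ranks is out of scope: those were computed over more methods than the
printed table contains.

## Synthetic data

`make_mtsc` builds per-(class, mode, channel) motifs as two-sinusoid
mixtures with class-specific frequencies/phases, blends every class
motif toward one shared motif by `inter_sim` (between-class similarity
is then controllable and motif distances shrink monotonically in it),
draws each case's mode uniformly (`n_modes_per_class` > 1 yields
multi-modal classes — exactly the regime the cluster-level loss
targets), adds i.i.d. Gaussian noise of sd `intra_var`, and truncates a
`ragged_frac` fraction of cases to random lengths in [l/2, l).
`make_localized_mtsc` builds two classes identical except for a
half-sine bump inside a given window — a dataset whose discriminative
time steps are known by construction.  `make_embedding_fixture` places
unit-norm source/target pairs around class axes on the hypersphere with
spread 1/separation, for loss-level tests.

What the generator does **not** emulate: real physiological waveform
structure (exercise bouts, recovery kinetics, cross-channel physiology),
non-stationary noise, or label noise.  Passing the synthetic studies
shows the pipeline recovers controllable class geometry; it does not
certify performance on real recordings.

## Validation studies and problem sizes

The packaged studies (`supcon_tsc.experiments`) run the full pipeline at
desk scale — filters (16, 32, 32), projection dim 32, batch 30, 15
stage-1 epochs, 100 full-batch stage-2 epochs, 5 seeds each — sizes
chosen so a study finishes in minutes on one CPU while leaving the
generator's conditions untouched:

- **Recovery**: 3 classes, n = 150, m = 3, l = 64, intra_var 0.3,
  inter_sim 0.2; held-out accuracy and silhouette of stage-1 embeddings
  vs raw flattened series (true labels).
- **Ablation direction**: same sizes with n_modes_per_class = 2,
  inter_sim 0.5; contrastive pre-training vs the cross-entropy baseline,
  counted as win-or-tie per seed.
- **Localization**: two classes differing only in t ∈ [20, 30); this
  study uses kernels (5, 3, 3) because attribution resolution is bounded
  by the receptive field — the default (8, 5, 3) three-block stack has
  an RF of ~40 steps, which would smear relevance far beyond a 10-step
  window; (5, 3, 3) keeps the RF commensurate with it.

## Known limitations

- float64 numpy training is orders of magnitude slower than a GPU
  framework; the package targets method-level correctness and small
  datasets, not benchmark-scale sweeps.
- Flat ARFF only (one value row per univariate case); the relational
  multivariate ARFF encoding is not parsed — use `.ts` or long CSV for
  multivariate input.
- The default encoder ignores the mask beyond zero-filling; strongly
  ragged datasets may benefit from `use_mask_channels=True`.
- Grad-CAM resolution is limited by the encoder's receptive field, and
  relevance is aggregated over channels.
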