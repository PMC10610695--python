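# Methods

This note documents the models and protocols `segssl` implements, the
defaults it ships, the numerical choices behind them, and what the bundled
synthetic benchmarks can and cannot demonstrate.

## Data model

A **segment** is one contiguous tri-axial accelerometer recording
containing a single activity; the activity label itself is optional and is
read only by the evaluation stage. Segments are sliced into windows of
length *L* at stride *S* (offsets 0, S, 2S, …; half-open 0-based slices),
producing exactly ⌊(T−L)/S⌋+1 windows from T samples. Segments shorter than
*L* are dropped with a warning, never padded: padding would fabricate
signal, and a recording too short for one window carries no usable
instance. Each window receives a globally unique instance label and its
segment's label; M ≤ N always, with equality exactly when every segment
yields one window. Defaults are L = S = 256 (2.56 s at 100 Hz,
non-overlapping); the synthetic benchmarks use L = 128, S = 64 at 50 Hz so
that a typical 8–18 s segment yields 5–13 phase-shifted windows. Optional
per-channel standardization (off by default) z-scores with training-set
statistics.

## Losses

**Segment discrimination (SD).** The memory bank holds one unit-norm
d-vector per segment. P(s|f) is the softmax over all M bank rows of
f<sub>j</sub>ᵀf / τ<sub>sd</sub>; the loss is the batch mean of
−log P(s<sub>i</sub>|f<sub>i</sub>). Two reduction choices are deliberate:

- the softmax denominator runs over **all M bank rows** — the bank's size
  equals the number of segment labels, and a softmax over anything less
  would not normalize over segments;
- the batch **mean** (not sum) is used so the loss magnitude is independent
  of batch size; the per-dataset total is a sum over all N instances, which
  is not computable per step anyway. Both the SD temperature
  (default 1, i.e. the plain non-parametric softmax) and the reduction live
  in `LossConfig`.

Gradients flow to the features only; the bank is a buffer updated after
each step by row ← normalize(m·row + (1−m)·mean of that segment's batch
features) with momentum m = 0.5, initialized to random unit vectors from
the run's seed. The exact momentum and initialization are conventions of
the instance-discrimination lineage rather than identified constants, so
both are config-exposed.

**FIS.** Applied to the raw batch feature matrix as printed: a sum over the
d per-dimension columns, no averaging and no column normalization. Its
minimum over unit-norm column sets is attained at orthogonal columns, where
it equals d·log(1+(d−1)/e) — a closed form the tests pin down.

**NT-Xent.** Cosine similarities over the stacked 2b views, self-similarity
excluded from each anchor's denominator (implemented by adding −10¹² to the
diagonal before the log-sum-exp, which is exact at float64), mean over all
2b anchors, temperature default τ = 1 (plain cross-entropy). All
log-sum-exp computations are max-shifted for stability, which also makes
the degenerate cases (M = 1, b = 1) exactly zero rather than zero up to
rounding.

**Combined.** λ₁L<sub>s</sub> + λ₂L<sub>sd</sub> + λ₃L<sub>fd</sub> with
λ = (1, 1, 1) by default. The contrastive term consumes the paired
f<sub>p1</sub> projections; SD and FIS consume the concatenated 2b batch of
f<sub>p2</sub> projections, with each view contributing its segment label.

## Architecture

Encoder: three 1-D convolutional blocks over time (valid convolution,
kernel 5 → batch norm → ReLU → max-pool 2; an odd-length tail sample is
dropped rather than padded), then global average pooling, so the last conv
width is the feature dimension d. Default channels (32, 64, 128) give
d = 128; the projectors are two-layer MLPs d → d with a ReLU hidden layer
and no internal normalization. f<sub>p2</sub>'s output is L2-normalized —
the normalization lives in the projector, not the encoder, so the
contrastive branch sees unnormalized projections and cosine similarity
normalizes where it is defined. The scaled-down benchmarks use channels
(16, 32, 64), i.e. d = 64: at ~500 training windows a 128-dim bank feature
adds cost without measurable benefit. The kernel/width/pooling details are
design choices of this package; only the three-block depth, the two
projectors and d = 128 are fixed points of the architecture family.

The whole stack runs on a small in-package reverse-mode autodiff engine
over numpy (`segssl.nn`): the model is small enough that a tape of ~100
array ops per step trains in seconds-to-minutes on one CPU, and a single
root seed (split into named streams for parameter init, bank init, data
order and augmentation draws) makes every run bitwise reproducible
single-threaded. Engine gradients are verified against central differences
(tolerance 1e-4) in the test suite.

## Augmentations

Fixed composition order jitter → scale → rotate → permute under one RNG
stream. Defaults: jitter σ = 0.05 (additive noise in signal units),
per-channel scaling factor ~ N(1, 0.1²) — channel-wise gain mimics device
orientation and sensitivity differences — uniform random proper 3-D
rotations (via quaternion sampling), and permutation into 4 contiguous
chunks of ≥ 10 samples. Two presets mirror the two standard recipes:
`hasc_like` = jitter + scale + rotate, `uci_like` = jitter + scale +
permute. Magnitudes are conventions, not identified values, and are never
hard-coded outside the config.

## Pretraining

One epoch is ⌈N/b⌉ batches. Discrimination methods (id/idfd/sd/sdfd)
shuffle instances each epoch and use a single augmented view per window;
contrastive methods sample b segments per batch (without replacement
within a batch when M ≥ b, so a segment never appears as its own negative)
and draw two distinct windows per segment when available, falling back to
the same window twice for singleton segments (which reduces those rows to
instance-based pairing rather than discarding them). ID/IDFD are literally
SD/SDFD with instance labels and a size-N bank — the same code path — so
the degeneracy "every window its own segment ⇒ SD ≡ ID" holds bitwise and
is tested as such. Optimizer: Adam, learning rate 0.01, default 150 epochs
(the benchmarks use 50 or 30; see below). The retained checkpoint is the
epoch with the lowest epoch-mean training loss, not the last epoch.
Non-finite loss aborts with a diagnostic rather than continuing.

## Evaluation

Few-shot transfer: k windows per class (default 10) drawn uniformly over
windows regardless of segment, a single affine head trained on the frozen
encoder's features (Adam, lr 0.001, 300 epochs, no augmentation), head
weights taken at the lowest validation loss, macro F1 on a held-out test
split. Per-class F1 is 0 when precision + recall is zero (including the
empty-class case). Trials reseed both the shot draw and the head
initialization. A `finetune` mode trains the entire model from random
initialization on the few shots (the no-pretraining baseline). On synthetic
data, splits are stratified by segment — the stand-in for the subject-wise
splits real deployments need — so windows of one recording never straddle a
split. Cross-domain transfer keeps the pretext window length and does not
resample signals across sampling rates; target segments shorter than one
window are dropped by the windowing stage.

## Synthetic data

Each class is a per-axis sum of sinusoidal harmonics plus white Gaussian
noise; a segment draws one phase per axis (mode `per_segment`), so windows
within a segment share spectral content and phase structure while segments
of the same class differ in phase — exactly the invariance the
segment-based losses are meant to exploit. The shipped `default4` preset:
4 classes at 50 Hz, fundamentals 1.0 / 2.0 / 3.5 / 5.0 Hz (within the
0.5–5 Hz band of everyday activities), axis-specific amplitudes, noise
σ = 0.3, 15 segments per class of 8–18 s. `default4_25hz` is the same
process at half the sampling rate for transfer exercises.

What this emulates: single-activity segments of variable duration,
within-segment phase diversity, class structure carried by spectral
content. What it does not: non-stationarity within a segment, gravity and
posture components, impacts, subject-level variation, label noise, class
imbalance. Consequently a passing benchmark shows the pipeline's machinery
and its ordering claims hold under the assumed structure — not that the
absolute F1 numbers transfer to real recordings.

## Benchmark problem sizes and known limitations

The two quality benchmarks (`segssl.benchmarks`) run on `default4` with the
(16, 32, 64) encoder and batch size 64: the recovery benchmark pretrains
`simclr_seg_sdfd` for 50 epochs (3 replicate seeds, 10-shot probes with 3
trials each) against a frozen random-init encoder; the pairing benchmark
trains `simclr_seg` and `simclr` for 30 epochs each on identical data and
seeds (5 replicates). These sizes were fixed once, as the package's own
desk-scale configuration.

Two observed properties of this configuration are worth stating plainly:

- **Random 1-D conv features are strong here.** A frozen random-init
  encoder probes at roughly 0.75–0.94 macro F1 on `default4`, because
  rectified random band-pass features after global average pooling already
  separate harmonic classes. The pretrained encoder reaches ~0.96–1.00, so
  the margin over random init is real but modest (~0.09–0.15 depending on
  seeds) and noisy in the random baseline. On real HAR data the analogous
  no-pretraining baselines range from far weaker to occasionally stronger
  than pretrained encoders, so this margin should be read as a sanity
  check, not an effect-size estimate.
- **Contrastive variants saturate.** With phase-randomized segments both
  pair definitions reach the F1 ceiling at these sizes, so the
  segment-vs-instance comparison typically resolves as a tie at 1.0 rather
  than a strict ordering.

Other limitations: no gyroscope/magnetometer channels; no automatic
segmentation of continuous multi-activity streams (explicit segment
structure is required at input); no BYOL-style negative-free baseline; no
learning-rate schedules or distributed training.
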