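# Methods

This note records the model, the choices that were genuinely open, and
what the desk-scale experiments do and do not demonstrate.

## Input pipeline

A 3-D scan is split into ordered 2-D slices along the scan axis
(default axis 0, configurable). For training, slices whose label
contains no foreground are excluded — the target appears only on a
central run of slices and empty ends carry no supervision; for
inference every slice is kept. Intensities are normalised per volume by
min–max scaling to [0, 1]: it is bounded, needs no dataset statistics,
and the encoder's normalisation layers remove any residual scale
sensitivity. Slices are resized bilinearly (masks with nearest
neighbour, so they stay binary) and grouped into consecutive
non-overlapping sequences of length T (default 8). A final short group
is padded by repeating its last slice rather than dropped — inference
must cover every slice — and the pad count travels with the sequence so
padded positions are excluded from loss and metrics. Batches are
five-dimensional, (N, T, C, H, W).

Supported formats: NIfTI (via nibabel) and NRRD (via SimpleITK), with
voxel spacing taken from the header. Label volumes coded 0/255 are
remapped to 0/1 at load time.

## Network

**Encoder.** A residual bottleneck encoder in the ResNet-50 layout
(stem 7×7 stride 2; stages of 3, 4, 6, 3 bottlenecks) emitting skips of
64, 256, 512, 1024, 2048 channels at strides 2…32. Batch normalisation
is replaced by group normalisation: desk-scale experiments use batch
sizes of 2–4, where batch statistics are meaningless, and group
statistics also remove the train/inference running-stats asymmetry —
freezing the CNN in stage 2 is then exactly "no parameter changes". The
encoder trains from scratch; a checkpoint hook allows loading external
weights but none are shipped.

**MSA placement.** The attention module sits on all five skips by
default. Its pyramid requires the skip to be at least 6×6; for small
test images the deeper skips fall below that, so the `reduced` preset
applies MSA to the two shallowest skips only. Inside the module the
order is: pyramid pooling first (C → 2C), then position and channel
attention in parallel on the fused map, combined as the sum of their
residual terms on the shared input (so at α = β = 0 the combination is
exactly the fused map), then a 1×1 projection back to the skip width.
The position/channel projections B, C use a 1/8 channel reduction; D
keeps full width. Position attention is O((H·W)²); above a configurable
grid (default 32×32) it is computed on an average-pooled copy and the
residual upsampled back, which preserves the identity-at-initialisation
exactly.

**Recurrence.** The decoder output (head width 64, `reduced`: scaled
down) feeds a bidirectional ConvGRU with hidden size equal to its input
width, 3×3 kernels, zero initial state — standard ConvGRU practice; the
concatenated 2C states pass through a 1×1 class head and softmax.
Padded positions run through the recurrence (keeping the step uniform)
and are masked out downstream. The recurrence-free variant used in the
ablation replaces the GRU + class head with a per-slice 1×1 head on the
same CNN features.

**Binarisation.** Foreground where the foreground probability strictly
exceeds the threshold (default 0.5); a tie goes to background, for
determinism.

## Loss

`L = L_dice + L_focal` on the foreground probability map. Dice is the
soft relaxation `1 − (2Σpg + s)/(Σp + Σg + s)` with smoothing
`s = 1e-6`; the set formulation is not differentiable, the soft form
is. Focal loss uses α = 0.25, γ = 2 (the customary values for dense
detection under heavy imbalance; the protocol this follows states no
values) with probabilities clipped to [1e-7, 1−1e-7] before logarithms.
Reduction: Dice over the pooled valid pixels, focal averaged per valid
pixel, then the two terms summed.

## Training protocol

Three stages, all SGD with momentum 0.9:

1. **CNN pretraining** through a temporary static 1×1 head on
   individual slices — 120 epochs, batch 16, lr 0.01 at full scale
   (desk-scale runs pass smaller numbers explicitly). The static head
   is discarded afterwards.
2. **Recurrence training** with every CNN parameter frozen
   (`requires_grad` off; the optimiser skips them, verified bitwise in
   the tests). Early stopping on the monitored loss with patience 10.
3. **Joint fine-tuning** at the smaller lr 0.001.

The step schedule halves the rate every 10 epochs (the halving factor
is a choice; only "decays every 10 rounds" is prescribed, and "rounds"
is read as epochs). Cosine annealing from 0.01 to 0.0001 is available
as the alternative schedule. Runs are bit-reproducible from the config
seed: data order, initialisation and updates all flow from seeded
generators, single-threaded.

Note one structural consequence of the staging: stage 2 starts with a
freshly initialised recurrence head, so its first-epoch loss can exceed
stage 1's first-epoch loss; within every stage the loss falls, and
stage 3 continues from stage 2's level.

## Phantom generator

Each phantom emulates the four properties of the target data regime:

- **continuity** — one elliptical target (aspect 1.5, fixed
  orientation) whose centre performs a small random walk (default
  σ = 0.6 px/slice) and whose area follows a smooth sine bump across
  slices; adjacent-slice mask IoU stays above 0.5;
- **scale variation** — the area profile spans a 4× range, so the
  largest slice exceeds the smallest by more than the 3× the tests
  assert;
- **low contrast** — the target sits only `contrast` (default 0.15)
  above background; distractor blobs are drawn from the *same* shape,
  size and intensity family as the target but re-placed independently
  on every slice, so within a single slice the target is nearly
  indistinguishable and only its persistence across slices identifies
  it. The target's starting position is uniform over the central 40%
  band, preventing a pure position shortcut;
- **imbalance** — the peak foreground fraction is capped at
  `fg_max_fraction` (default 0.08, validated < 0.10) with headroom, and
  the configuration is rejected if the smallest slice's target would
  degenerate below a 2-px semi-axis.

Gaussian noise (default σ = 0.03) is added and intensities clipped to
[0, 1]. What the phantoms deliberately do not model: MRI physics (bias
fields, coil profiles, partial volume, motion), anatomy-shaped targets,
and 3-D coherent distractor structures. Passing tests on phantoms
therefore demonstrate that the architecture and optimisation behave as
designed under the stated statistical regime — not clinical-grade
accuracy on real scans.

## Desk-scale experiments

Problem sizes were chosen so the full suite runs on one CPU core in
minutes: 32×32 slices, T = 4, `reduced(8)` widths (8…256 channels, one
bottleneck per stage).

- **Overfit run** (`overfit_experiment`): one phantom, two sequences,
  140 epochs across the three stages. The untrained network scores
  about the foreground prior (≈ 5% Dice); the trained one exceeds 95%
  (measured 99.6%). This validates the end-to-end gradient path, not
  generalisation.
- **Recurrence ablation** (`recurrence_ablation_experiment`): per seed,
  5 phantoms (4 train / 1 validation, the 4:1 convention) under
  high-continuity conditions — jitter 0.3, noise 0.08, two same-family
  distractors — chosen so per-slice evidence is noisy while temporal
  integration across neighbouring slices is informative. The full model
  and the recurrence-free variant train with the same total epoch
  budget (the static variant receives the three stages' combined
  epochs). Across five seeds the median validation Dice of the full
  model exceeded the static variant's (57.4% vs 53.5% on the test
  seeds). The claim is the *direction* — sequence context helps when
  continuity is the distinguishing cue — not any magnitude; single
  seeds can go either way at this scale.

## Metrics

Dice and IoU are computed on pooled voxels per volume; both-empty pairs
score 100 (perfect agreement), empty-vs-nonempty scores 0. Hausdorff is
the exact symmetric maximum (no 95th-percentile relaxation) between
foreground voxel-centre point sets at integer 0-based coordinates,
scaled by spacing when given, computed in 3-D per volume (a per-slice
breakdown is available); it is reported as *missing* — never a sentinel
number — when either mask is empty. The implementation uses scipy's
directed Hausdorff routine and is tested against an all-pairs
brute-force oracle.

## Numerical notes

The autodiff engine keeps whatever float dtype the inputs carry:
networks train in float32, while the ConvGRU reduction test runs in
float64 to meet its 1e-10 tolerance. Convolution is im2col + BLAS
matmul with a pointwise fast path; its backward pass scatters window
gradients with one slice-add per kernel offset. Bilinear resampling
uses half-pixel-centre alignment and, being linear, backpropagates
through the transposed interpolation matrices. Softmax subtracts a
detached row maximum for stability. Group counts for normalisation pick
the largest of {8, 4, 2, 1} dividing the channel width.

## Known limitations

- CPU-only and modest problem sizes; full-scale (512×512, T = 8,
  ResNet-50 widths) forward passes work but training at that scale is
  impractical without an accelerator.
- Binary segmentation only (target vs background); no multi-chamber
  support.
- No DICOM series assembly, bias-field correction or registration; the
  input contract starts at oriented 3-D volumes.
- The Hausdorff metric is the exact maximum and is therefore sensitive
  to single outlier voxels; that is intentional (it matches the stated
  evaluation) but HD95 is often preferred in practice.
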