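# Methods

`reefblocks` implements a family of detection and forecasting building
blocks for coral reef health monitoring, together with the synthetic scene
generator and training harness needed to exercise them end to end on a
single CPU.  This note records the models, the parameters that matter, the
numerical choices, and what the bundled experiments do and do not show.

## The scientific setting

Reef monitoring imagery poses two chronic problems for object detectors:
extreme object-scale variation (a survey frame mixes whole colonies with
centimeter-scale bleached patches) and stochastic optical conditions
(turbidity, illumination gradients, blue-green color casts).  Coral health
is annotated as an ordinal four-state variable — Healthy (0), Sub-healthy
(1), Bleached (2), Dead (3) — and, for multi-year site series, the goal is
to forecast next year's state map from the two preceding years.

## Detection blocks

### Local-Global Attention (LGA) and the holistic attention head

The LGA unit tokenizes a feature map into non-overlapping p x p patches
(p = 2 and 4 in the two parallel units).  Each patch is reduced **across
channels** by mean pooling to a p^2-vector, encoded by a two-layer MLP into
a C-vector `l_j`, and self-gated: `l'_j = l_j * softmax(l_j)` (softmax over
the C components of that patch alone — the only axis that keeps the
operation per-patch).  A learnable global prompt `P_g` then scores each
patch by clamped cosine relevance

    m_j = clamp( l'_j . P_g / (|l'_j| |P_g| + eps), 0, 1 ),

which is in [0, 1] for any finite input and safe at zero vectors.  The
gated features `m_j l'_j` pass through a learnable C x C map applied
per-patch over channels, are reassembled on the patch grid, bilinearly
upsampled to the input resolution, and mixed by a 1 x 1 convolution.
Non-divisible spatial sizes are right/bottom zero-padded to the next
multiple of p and cropped after upsampling.  `P_g` is initialized
unit-normal scaled by 1/sqrt(C) so initial cosines are small.

The holistic attention block (HAB) fuses six pathways additively: a 1 x 1
skip projection, the three stages of a sequential 3 x 3 convolution chain,
and the two LGA units applied to the skip map; the sum is refined by
efficient channel attention (1-D convolution of kernel 3 over the GAP
descriptor), spatial attention (7 x 7 convolution over channel mean/max
maps), batch norm and ReLU.  Convolution blocks elsewhere are
conv + batch norm + SiLU.  The detection head stacks two HABs per pyramid
level (strides 8/16/32) before lightweight 1 x 1 classification and
regression convolutions.  The two stacked HABs keep independent LGA
prompts, and the head is shared-then-split (one HAB stack feeding both
1 x 1 branches); both points were genuinely open and are implementation
choices here.

### Monte Carlo channel attention

Training context: a fresh random permutation of spatial positions (one per
sample, shared across channels so cross-channel alignment survives for the
channel attention that consumes it), adaptive average pooling to p x p with
p drawn uniformly from {1, 2, 3} per forward call, and — for p > 1 — one
uniformly chosen cell.  Inference context: exact global average pooling,
consuming no randomness (asserted in tests by a counting RNG).  Both phases
share a two-layer 1 x 1 bottleneck (reduction 16, floored at one channel)
with sigmoid output multiplying the input channelwise.  For p = 1 the
training branch equals the inference branch bit-for-bit.

### Fourier-synthesized dynamic downsampling

Each sample's downsampling kernel is synthesized in the frequency domain:
a softmax-weighted sum (weights `alpha_i`, drawn per sample) of K = 16
learnable basis spectra supported on the central 8 x 8 block (64
coordinates) of a 16 x 16 grid.  The synthesized spectrum is Hermitian-
symmetrized so its inverse FFT is real (the imaginary residue is asserted
below 1e-6 and discarded), fftshift-centered, cropped to a 4 x 4 kernel and
normalized by its absolute sum plus 1e-6.  The kernel is applied depthwise
(one kernel per sample, shared across channels) with stride 2, followed by
a pointwise 1 x 1 channel-mixing convolution.  Grid size 16, kernel size 4
and the softmax law for alpha are free choices: the central-8x8 support
requires a grid larger than 8, a 4 x 4 stride-2 kernel covers the input
evenly, and a simplex-valued alpha keeps kernel scale bounded.  At
evaluation alpha is fixed to the uniform vector so inference is
deterministic, mirroring the dual-phase attention; a content-conditioned
alpha head (GAP -> linear -> softmax) is available via
`SFDConvConfig(alpha_mode="content")` because the randomness-versus-
input-adaptivity question is genuinely underdetermined.

### Scale-aware dynamic box loss

For a ground-truth box of normalized area beta = (w h)/(W H) and a fixed
trade-off delta (default 0.5), the CIoU-style loss

    L = (1 - IoU) + (1 + delta - beta) R_DIoU + (1 - delta + beta) R_CIoU

shifts weight from the center-distance penalty (small targets) to the
aspect penalty (large targets); the two weights always sum to 2, and at
beta = delta the loss is the plain CIoU loss.  R_DIoU is the squared
center distance over the squared enclosing-box diagonal; R_CIoU is the
arctan aspect term with its alpha balance treated as a constant during
differentiation, as in the reference CIoU formulation.  beta is clipped to
[0, 1] in case augmentation pushes a box beyond the frame.

## Detection harness

The host network is a small CSP-style backbone (stem plus four stride-2
stages, widths w/2w/2w/3w/4w) and a PANet-style neck; the dynamic
downsampling replaces the three deepest backbone stride-2 convolutions,
Monte Carlo attention sits after backbone stages 3-4 and each neck fusion
output, and the head is either the stacked-HAB head or a plain two-conv
tower (feature flags make all eight ablation combinations buildable).
Assignment is anchor-free and one-to-many: each box belongs to exactly one
pyramid level, chosen by its longest side (level 0 up to 3 x 8 px, level 1
up to 3 x 16, level 2 otherwise) so that the bounded decode below can
always represent it; at that level every cell whose center lies inside the
box is positive, ambiguity resolves to the smallest box, and a box
covering no cell center falls back to the nearest cell of its level so
sub-stride colonies stay learnable.  Regression uses the bounded
center-offset decode: the box center is the cell center plus
(2 sigmoid - 1) x stride per axis and each side is (2 sigmoid)^2 x stride,
so a predicted box need not contain its cell center (essential for
objects smaller than one stride) and sizes are capped at four strides,
which is why level choice keys on box size.  Classification is plain
sigmoid binary cross-entropy — the YOLO-family objective — with the
standard -log(99) bias prior, a positive-term weight of 5 against the
roughly 20:1 background/foreground cell imbalance, and normalization by
the positive count.  Total loss weights are box 7.5 / cls 0.5; there is no
distribution-focal term because box geometry is regressed directly.
Capacity evaluations emit detections from score 0.001: COCO evaluation is
rank-based with a 100-detections-per-image cap, and a higher floor would
silently discard weak true positives.  Training is AdamW (beta1 0.937, weight decay
5e-4) under a cosine schedule with warm-up.  Inference applies class-wise
NMS at IoU 0.65, 100 detections per image.  Evaluation follows the COCO
protocol exactly (ten IoU thresholds 0.50:0.05:0.95, 101-point
interpolation, 32^2/96^2 area cutoffs), implemented in
`reefblocks.cocoeval` and verified against a brute-force PR enumeration.

Two numerical points matter in the desk-scale regime.  First, all neural
computation runs on the package's own NumPy reverse-mode autograd engine
(`reefblocks.nn`) in float32; every layer's gradient is checked against
central differences in the test suite.  Second, batch normalization in
very small batches leaves a gap between per-batch training statistics and
lagging running averages, which ruins eval-mode predictions of a memorized
model; after training the harness therefore re-estimates the statistics
with one forward pass under the final weights (`recalibrate_bn`), the
standard population-statistics correction.  Memorization experiments use
full-batch training so that normalization is consistent across steps —
with 16-image batches the per-batch and population statistics coincide.

## Forecasting stream

Frozen features: the trained (or at desk scale, fixed randomly initialized)
detector supplies P4 neck features at stride 16 — 40 x 40 for 640-pixel
imagery, 8 x 8 for the 128-pixel fixtures used in the bundled experiments.
The extractor is wrapped so its outputs are detached; an assertion verifies
every epoch that no parameter of the detector accumulated a gradient.

The forecaster is a two-layer ConvLSTM (3 x 3 gates, hidden size 256 at
full scale; 16-32 in the desk experiments) run over the two-step feature
sequence, followed by a 1 x 1 convolution and channel softmax producing a
(B, 4, H, W) probability map.  The gate equations are the standard
ConvLSTM update; the test suite holds them to a literal per-pixel loop
within 1e-6.  Ground truth is the year-3 annotation rasterized on the
feature grid: a cell takes the label of any box containing its center,
overlaps resolve by severity (Dead > Bleached > Sub-healthy > Healthy),
and uncovered cells are background (255).  The head emits four state
channels; background cells are excluded from the cross-entropy and from
every metric, which reconciles a four-channel output with a raster that
contains a background value.  Training: AdamW, lr 1e-4, cosine annealing,
100 epochs at full scale; pixel-wise cross-entropy; sites are split as
whole units and an exception is raised if a site id appears in two splits.

Baselines and metrics: a persistence baseline (year 3 = year 2); a
first-order Markov baseline whose 4 x 4 row-stochastic matrix is estimated
from per-cell transitions on training rasters (uniform rows where a state
was never seen; prediction is the row argmax with ties broken toward the
worse state).  The metric battery reports pixel-wise forecasting accuracy
(PFA) over labeled cells, per-class precision/recall/F1 and macro-F1,
ordinal MAE (|predicted state - true state|, computed where both rasters
are labeled), and transition-specific accuracy grouped by the observed
(year 1, year 2) cell states, including an aggregate recovery group
(any non-Healthy -> Healthy).  Per-pixel grouping is used because the
natural sample unit of a 40 x 40 raster is the cell.

## Synthetic reef generator

Scenes are textured low-frequency value-noise seabeds with colonies drawn
as clusters of one to three overlapping ellipse lobes, colored by state
(Healthy brown-green, Sub-healthy pale, Bleached white, Dead gray) with
multiplicative texture, and tightly boxed.  Colony footprints are drawn
from a two-component size law: with probability 0.6 a "small" footprint
(normalized side 0.015-0.04, below the COCO small-object cutoff of
32^2 px at 640^2) and otherwise a "large" one (0.1-0.35); the gap between
the ranges keeps the small-object bias crisp after pixel snapping, and the
0.6 default encodes the strongly small-object-biased area histogram of
real reef survey data.  Site series re-render the same colonies across
three years with positional jitter at most 2% of the frame (object
identity is positional, not instance-tracked), year-1 states from a
configurable initial distribution and later years from a user-supplied
row-stochastic transition matrix.  Degradations: Gaussian blur plus
contrast compression (turbidity), a multiplicative illumination ramp
(low light), and red/green channel attenuation (color cast); strength 0 is
exactly the identity.

Every output is a pure function of (config, seed).  The generator emulates
the *statistical* structure detection and forecasting code cares about —
scale mixture, color-state coupling, Markov health trajectories, overlap
and turbidity — and nothing else: no photorealism, no annotation noise, no
instance appearance variation, no class imbalance drift across years.
Consequently, passing tests demonstrate that the blocks compute what their
equations say and that the pipeline can learn and forecast under known
dynamics; they say nothing about accuracy on real reef imagery.

## Problem sizes in the bundled experiments

The test suite and `scripts/acceptance.py` size the experiments for a
single CPU: memorization capacity uses 16 scenes at 320 x 320 with a
width-8 model trained in 100-epoch warm-restart stages (batch 8) until
its training-set AP50 converges, at most 600 epochs; learning-versus-
persistence uses 60 training and 30 test sites at 128 x 128 (8 x 8 feature
grid, hidden size 24, 80 epochs, three seeds); Markov recovery uses 500
sites; the stochastic-law checks use 10^4 and 3 x 10^3 draws; the ablation
grid trains each of the eight flag combinations for one epoch at 96 x 96.
The transition matrix used for forecasting fixtures is strongly state-
dependent (Healthy row [0.8, 0.2, 0, 0]; Sub-healthy [0, 0.15, 0.85, 0];
Bleached [0, 0, 0.1, 0.9]; Dead absorbing), so persistence is a beatable
but non-trivial reference.

## Known limitations

* The NumPy engine is single-threaded apart from BLAS; it is sized for the
  bundled experiments, not for full-scale training.
* The dynamic-downsampling spectrum/kernel geometry (16 x 16 grid, 4 x 4
  kernel) and the law of alpha are package choices where the design space
  was genuinely open.
* Forecasting experiments at desk scale use a frozen randomly initialized
  backbone as the feature source; its features are fixed and rich enough
  to decode colony color states, but they are not detection-optimized
  features.
* Mosaic and MixUp augmentations are not implemented; horizontal flip and
  HSV jitter are available but off by default in the bundled experiments.
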