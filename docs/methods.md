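# Methods

This note documents the models and procedures implemented in `rootct`,
the assumptions behind them, the synthetic phantom that stands in for
real scans, and the choices made where the design was genuinely open.

## Intensity normalisation

A reconstructed CT volume of a pot of granular substrate has a bimodal
intensity histogram: an air mode (head space above the soil, and any
region outside the pot in the field of view) and a soil mode. Min/max
rescaling would make the 8-bit output depend on outliers (dense mineral
grains), so the rescale is anchored on the two modes instead: air → 0,
soil → 128, linear in between, rounded half-away-from-zero and clipped to
[0, 255]. Clipped values come from air or mineral contaminants and carry
no root information.

Peak finding uses a 256-bin histogram of the raw values smoothed with a
Gaussian of 2 bins bandwidth; the two tallest local maxima at least 10
bins apart, each with prominence ≥ 20 % of the tallest mode, are the air
and soil peaks. The prominence floor is what separates a genuine second
mode from sampling wiggle on the flank of a unimodal histogram; a volume
without two qualifying maxima is rejected explicitly rather than guessed
at. For integer data the peak is refined to the most frequent raw value
inside the winning bin.

Cropping keeps the centred square prism of side `2*floor(r/voxel) − 1`
(odd, centred on a voxel) across the full stack height: at a 9 cm radius
and 0.3 mm voxels this is the 599-voxel plane of the full protocol. The
crop's purpose is to discard the region at the pot wall, where roots
deflect and carry little varietal information. An optional circular mask
zeroes voxels outside the radius; the default output is the square prism.
Rescaling and cropping commute (one is pointwise, the other geometric);
the pipeline applies the rescale first.

## Conventional prefilter

The prefilter is 3-D median filtering (default 3³ kernel, mirror-padded
boundaries) followed by edge detection. The edge operator is the 3-D
Sobel gradient magnitude `sqrt(Gh² + Gw² + Gd²)` with the three
axis-aligned 3×3×3 Sobel kernels, normalised by 32 so the response to a
unit ramp matches central differences; a plain central-difference
operator is available behind the same interface. The magnitude is
invariant to constant intensity offsets and homogeneous in amplitude.
Output is re-quantised to 8 bits (clip-and-round), optionally stretched
so the maximum response maps to 255, so filtered volumes feed the same
tiling/training path as unfiltered ones. Which exact edge operator the
original visualisation tool uses is not published; Sobel magnitude is
adopted as the canonical intensity-based edge detector and the choice is
kept pluggable.

## Tiling

Whole volumes do not fit a 3-D network, and predictions near tile faces
are unreliable. Volumes are therefore divided into `tile`³ sub-volumes
(default 64) of which only the central *unique core* (`tile − 2·margin`,
default 48) is kept at reassembly; the 8-voxel margin shell is computed
but discarded. The core lattice is anchored at voxel 0 with stride equal
to the core side; trailing cores are truncated at the volume end, and
source windows extending outside the volume are reflect-padded (zero and
edge-replicate padding are available). This anchoring reproduces the
full-protocol count 18 × 13 × 13 = 3042 for an 860 × 599 × 599 volume and
guarantees that the cores partition the volume exactly: reassembly is
the identity, and no output voxel depends on any margin voxel (verified
by sentinel poisoning in the tests). Overlap-averaged blending is
deliberately out of scope — overlaps are deleted, not blended.

## Segmentation network

The model is a fully convolutional voxel-wise residual network in the
VoxResNet family, indexed `(N, C, H, W, D)`:

* stem: two 3³ convolutions (width `w = base_width`), each BN + ReLU;
* encoder: stride-2 3³ convolution to width 2w, then pre-activation
  residual blocks (BN→ReLU→conv, BN→ReLU→conv, identity skip); a second
  stride-2 convolution to width 4w with further blocks (total
  down-sampling ×4);
* decoder: 2× transposed convolutions (kernel 2, stride 2) back through
  widths 2w and w, with residual blocks after each; BN + ReLU and a 1³
  output convolution;
* head: sigmoid for the single root class; the restoration variant is
  the identical trunk with the output non-linearity removed.

With the default block schedule (2, 3, 2, 2) the countable depth —
convolutions plus transposed convolutions on the main path — is 25. The
convention for "countable" includes only (transposed) convolution
layers, not BN/activations. Deep supervision (auxiliary full-resolution
logits from the two coarse stages, fused by summation before the head)
is implemented but off by default, since the production model has a
single sigmoid output.

The sigmoid head's bias is initialised to −3 (foreground prior ≈ 5 %):
root voxels are rare, and a balanced initialisation floods the volume
with false positives that Dice loss is then slow to remove. Input sides
must be divisible by 4 (two stride-2 stages); anything else is rejected
with a shape error rather than silently cropped.

Batch normalisation uses batch statistics in training and running
averages (momentum 0.1) at evaluation. This matters at desk scale, where
batches are small: single-tile batches make training statistics
tile-local while evaluation statistics are global, which systematically
miscalibrates the air region. The desk-scale batch of 9 mixed tiles
avoids this.

The layers themselves (3-D convolution via an `(C·k³) × (N·HWD)` im2col
buffer and one BLAS matmul, kernel-2/stride-2 transposed convolution,
BN, ReLU, sigmoid) and Adam are implemented in `rootct.nn` on numpy, in
float32 by default and float64 for gradient checking; every analytic
backward pass is verified against central finite differences in the test
suite. The first convolution of a network skips its input-gradient
computation (nothing consumes it).

## Training

Both tasks share one loop: Adam at a constant learning rate (no
scheduler), full shuffle without replacement each epoch,
`ceil(n/batch)` iterations per epoch including the final partial batch
(3042 tiles at batch 64 → 48 iterations), optional random per-axis flips
applied identically to input and target, per-epoch mean loss recorded,
and bit-reproducibility given the seed. A non-finite loss aborts with a
diagnostic rather than training through NaNs.

* **Segmentation**: soft Dice loss
  `1 − (2Σpt + s)/(Σp + Σt + s)` with `s = 1e-6`, computed on sigmoid
  probabilities (no thresholding during training; the 0.5 threshold
  appears only at prediction). The batch loss is a single Dice ratio
  over the whole batch rather than a per-sample mean: on a tile with an
  all-background target the per-sample Dice gradient is O(s), so a
  per-sample mean starves background tiles of training signal and false
  positives there are never penalised. Defaults: learning rate 1e-4,
  batch 64, 1500 or 3000 epochs, flips on.
* **Restoration (Noise2Clean)**: mean squared error between the
  head-less network output on a noisy tile and the aligned clean tile.
  Defaults: learning rate 1e-5, batch 64, 500 epochs, flips off. Pairs
  must be voxel-aligned; the loader asserts equal shapes and refuses to
  register misaligned volumes.

Training with CT and prefiltered volumes together is supported by
pooling both tile sets into one single-channel dataset (the alternative
2-channel reading is not asserted anywhere).

## Evaluation

Confusion counts (TP/FP/FN/TN) are computed voxel-wise on entire
reassembled volumes, never on sub-tiles. Precision `TP/(TP+FP)` and
recall `TP/(TP+FN)` return an explicit undefined marker (`None`) on an
empty denominator — never a silent 0 or 1. Dice is the harmonic mean
`2PR/(P+R)`, algebraically equal to `2TP/(2TP+FP+FN)`; the both-zero
case is 0 by convention. Table values are rounded half-away-from-zero to
3 decimals. PSNR is `10·log10(max²/MSE)` in dB, flagged infinite for
identical inputs. The improvement statistic between a baseline loss A
and a treatment loss B is `100·(A−B)/A`. A qualitative comparison volume
(white TP / blue FP / red FN over black) can be written as an RGB slice
stack.

## Synthetic phantoms

The generator emulates what the pipeline actually consumes, not CT
physics. A phantom is a raw16 volume with:

* granular soil at `soil_level` (default 20000) with spatially
  correlated texture (white noise smoothed at ~1.2 voxels, scaled to
  `soil_texture_sigma = 1200`);
* an air gap (top 10 % of slices) and the region outside the pot
  cylinder (radius 95 % of the half-plane) at `air_level = 2000`;
* crown roots starting near the top centre, grown as biased 3-D random
  walks (downward pull `downward_bias`, angular jitter `tortuosity`,
  unit step) and rasterised as tubes of radius 2–3 voxels by stamping
  spheres along the centreline — the Boolean label is exact by
  construction; optional lateral branching (off by default, matching
  training data in which laterals are essentially absent);
* roots darker than soil (`root_level = 9000`): water-filled tissue in a
  drained granular matrix attenuates less than the calcined substrate.
  The contrast sign is configurable since it is substrate-dependent.

Intensity levels were chosen once so that, on the 8-bit scale, air ≈ 0,
roots ≈ 50 and soil ≈ 128 with texture σ ≈ 8.5 — comfortably bimodal for
peak finding, with root/soil contrast an order of magnitude above the
texture, as in a well-exposed scan.

Scan-time degradation is additive zero-mean Gaussian noise (σ in raw16
units) followed by an optional 3×3 in-plane box blur emulating detector
binning; the degraded volume stays perfectly voxel-aligned with its
clean source, so noisy/clean pairs are valid Noise2Clean training data.
A scan series shares a single clean phantom and label across noise
levels, like repeated scans of one fixed pot.

What the phantom does *not* model: beam hardening, ring and streak
artefacts, partial-volume blur at root boundaries, soil moisture
gradients, and reconstruction-correlated (non-white) noise. Passing the
phantom experiments therefore demonstrates that the pipeline mechanics
and optimisation behave correctly, not that the trained weights would
transfer to real scans.

## Desk-scale experiments

The full protocol (3042 tiles of 64³, batch 64, 1500+ epochs) is a
multi-day GPU workload. The experiment harness
(`rootct.experiments`) runs the same pipeline at a size a single CPU
completes in minutes, and all end-to-end results in this repository are
produced at this scale:

* phantoms: 96³ (`tiny` preset); one training phantom and one held-out
  phantom from the same specification, differing only in generator seed
  — mirroring the two-pot protocol (one pot for training, one for
  evaluation);
* preprocessing: peak-anchored rescale, then a 40-voxel (12 mm) pot
  crop, trimmed (centred) to 96 × 72 × 72 so the 24³ training-tile
  lattice covers the analysis volume exactly — border strips that no
  training tile ever saw would otherwise leak false positives into the
  evaluation. Noisy members of a scan series are rescaled with the
  *clean* member's histogram anchors: the volumes are aligned, the
  ground truth comes from the clean (long) scan anyway, and at the
  strongest noise level the noisy member's own histogram is no longer
  bimodal;
* network: `base_width 4`, one residual block per stage (13 countable
  layers on the main path), with deep supervision enabled for
  segmentation: with only ~200 optimisation steps the auxiliary
  coarse-stage outputs markedly stabilise training across seeds by
  shortening the gradient path to the encoder — and multi-level fused
  outputs are how the cited architecture family was originally built.
  The restoration trunk stays single-output;
* training: all 36 tiles (4 × 3 × 3 per volume, 24³ each), batch 9 so each
  soft-Dice step mixes root, soil and air tiles, 50 epochs, learning
  rate 1e-2 for segmentation and 3e-3 for restoration — the shorter the
  schedule, the larger the stable constant learning rate; both rates
  were fixed by a brief stability pilot, the same procedure the full
  protocol reports for its own rate. After the last epoch the
  batch-norm running statistics are re-estimated in one momentum-1/k
  pass over the training tiles, since exponential averages lag the
  final weights on short schedules;
* inference: standard 64³ tiles with 8-voxel margins;
* restoration: noisy input at σ = 5000 with binning blur (emulating the
  shortest, binned scans — strong enough degradation that the noisy
  baseline leaves the restorer real headroom), both members of each
  pair normalised against the clean volume's histogram peaks so the
  mapping is pure denoising.

## Numerical and degenerate-input choices

* Rescale rounding: half away from zero; only the anchors and clipping
  are externally constrained.
* Median/edge boundary handling: mirror reflection (edge voxel not
  duplicated), avoiding artificial face edges.
* Dice smoothing 1e-6: keeps all-background tiles at loss 0 instead of
  0/0 in the `dice_loss` contract.
* Histogram peak finding: explicit failure on unimodal/constant input.
* `iterations_per_epoch`, tile counts: ceilings, so partial batches and
  truncated trailing cores are included, never dropped.
* Checkpoints embed the architecture config and refuse to load into a
  mismatched one.
* Determinism: all randomness flows from explicit seeds
  (`numpy.random.default_rng`); two runs with the same seed, config and
  machine produce identical loss curves.

## Known limitations

* The numpy engine is single-device and unsuited to the full-scale
  protocol; it exists for correctness, testing and desk-scale studies.
* Only the cpu device tag is accepted; there is no mixed precision and
  no data parallelism.
* The phantom's realism limits (above) mean desk-scale metric *levels*
  should not be compared with real-scan tables; only mechanisms,
  orderings and qualitative effects carry over.
* Lateral roots are essentially absent from default phantoms, so — as
  with the real training data — models trained on them will miss
  laterals.
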