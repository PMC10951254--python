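# Methods

## Problem and model

Invasive coronary angiography projects iodinated contrast medium onto an
X-ray detector: the arterial tree appears as a faint, curvilinear darkening
over a noisy, unevenly illuminated background, frequently crossed by ribs
and by the contrast-filled catheter. `angioseg` segments that tree
pixel-wise and, because the left (LCA) and right (RCA) coronary arteries
are imaged in separate injections with quite different morphology, first
routes each image through a binary side classifier so that a per-side
segmentation model can be applied.

The segmentation network, SE-RegUNet, is a U-Net whose encoder is a RegNet
and whose decoder blocks carry squeeze-and-excitation (SE) channel
attention:

* **Encoder.** RegNet stage layouts follow the quantized linear rule of the
  RegNet design space: per-block widths `w_j = w_0 + w_a · j` are snapped to
  a geometric grid with ratio `w_m`, rounded to multiples of 8 and made
  divisible by the group width. For the 16-GFLOP variant we use the
  published RegNetY-16GF parameters (depth 18, w₀ = 200, w_a = 106.23,
  w_m = 2.48, group width 112), which the generator resolves to stage
  widths (224, 448, 1232, 3024) with depths (2, 4, 11, 1); blocks are
  Y-style grouped bottlenecks (bottleneck ratio 1, SE, residual
  throughout). For the 4-GFLOP variant no canonical public "RegNetZ" config
  exists at that compute point, so we define it inside the same design
  space with inverted-bottleneck Z-style blocks (expansion 4, grouped 3×3,
  SE on the expanded width, linear projection, residual only at stride 1):
  stem 32, widths (56, 112, 272, 576), depths (2, 6, 12, 2), group width 8.
  This configuration performs 3.8 GMACs on a 256×256×3 input, i.e. it sits
  at the 4-GFLOP design point its name declares.
* **Decoder.** Each stage upsamples ×2 (bilinear, half-pixel centres),
  concatenates the encoder skip at that resolution, applies two
  conv3×3–BatchNorm–ReLU layers and an SE gate (reduction 16). The stem
  (stride-2) features serve as the shallowest skip; a final ×2 upsample,
  conv block and 1×1 head produce two class maps at full resolution,
  normalized per pixel by softmax. Decoder widths, deepest to shallowest,
  default to (288, 144, 72, 36, 18) for the 4GF backbone and
  (1792, 512, 256, 96, 48) for the 16GF backbone. These widths were
  calibrated so that total complexity sits at the intended design points —
  30.7 M parameters / 28.6 GFLOPs at 512² for the 4GF model and 193.9 M
  parameters for the 16GF model — since a U-Net taper leaves this choice
  open. Bilinear (not transposed-conv) upsampling avoids checkerboard
  artifacts and parameters.
* **Side classifier.** The same encoder followed by a 2×2 *quadrant*
  average pool and a linear–sigmoid head. Plain global average pooling was
  deliberately rejected: it is translation-invariant, and the decisive cue
  for laterality is *where* the tree enters the frame; pooling each spatial
  quadrant separately preserves that coarse geometry at any input size.

### Complexity accounting

`profile_complexity` pushes a shape-only probe through the model's own
forward code, so the layers counted are exactly the layers executed.
Parameters are the exact sum of trainable elements; FLOPs count one
multiply-accumulate as one operation (the convention under which a "4GF"
backbone performs ≈4×10⁹ at classification resolution), evaluated by
default at 512×512×3.

## Preprocessing

`preprocess_pipeline` = unsharp mask, then two CLAHE filters applied to the
USM output, stacked as a 3-channel image. All operators work on 8-bit
intensities (256 histogram bins); float images in [0, 1] are rescaled in
and out.

* **USM**: `out = clip(x + amount · (x − G_σ x))` with Gaussian σ =
  `usm_radius` (default 2.0 px) and gain `usm_amount` (default 1.5).
* **CLAHE**: per-tile histograms are clipped at `clip_limit` × the uniform
  bin height, the excess is redistributed uniformly, and per-tile CDF
  look-up tables are blended bilinearly between tile centres. Images not
  divisible by the grid are mirror-padded and cropped back. Defaults:
  filter A clip 2.0, 8×8 tiles; filter B clip 4.0, 16×16 tiles — ordinary
  values for 512² X-ray frames; the pipeline structure, not these
  constants, is the contract, and all are configurable. With one tile and
  an unbounded clip limit the operator reduces exactly to global histogram
  equalization, which the tests exploit as an oracle.

Whether the first channel should be the raw or the sharpened image, and
whether the two CLAHE filters chain or branch, is under-determined; we
chose USM output as channel 1 and parallel CLAHE branches, reading the
enhancement as one serial USM stage feeding two parallel local-contrast
views.

## Loss

Vessel pixels are 1–10 % of an angiogram. The training loss is a
class-weighted focal loss,

    FL = α (1 − p_t)^γ · ( −w_y log p_t ),   mean over pixels,

with α = 0.8, γ = 2, class weights (background 1, vessel 20), and p_t the
predicted probability of the pixel's true class, clamped at 1e−7. The
printed form of this loss inserts the scalar weighted cross-entropy where
the standard focal loss has p_t; read literally it would take the logarithm
of a loss value. We implement the standard reading (which recovers the
printed form when "WCE" denotes the cross-entropy's inner probability) and
keep the literal scalar composition available behind
`FocalLossParams(literal_form=True)` for comparison. The class weight
multiplies the log term (inside the cross-entropy); with γ = 0, α = 1 the
loss reduces exactly to the weighted cross-entropy.

## Metrics

Dice 2|X∩Y|/(|X|+|Y|) on argmax-binarized maps (equivalent to thresholding
the vessel channel at 0.5); sensitivity, specificity, accuracy and
precision from pixel-wise confusion counts with vessel as positive; ROC
AUC as the normalized Mann–Whitney U with half-credit ties. Conventions:
both-empty Dice is 1.0 (perfect agreement on absence; flagged in reports);
ratios with zero denominators are reported as flagged nulls and excluded
from the mean ± SD aggregation. Reports serialize to JSON and CSV (one row
per image plus aggregate rows).

## Training protocol

Defaults mirror the study protocol: 200 epochs (100 for external-validation
runs), batch 8, 512×512 inputs, learning rate 1e−3, five-fold
cross-validation over the 80 % training/validation portion with a 20 %
held-out test set. Splitting is deterministic given a seed, by patient
when patient ids exist (all frames of one acquisition in one split), and
accepts explicit count overrides because the published 619 → 510/109
allocation does not match an exact 80/20 fraction — we do not guess the
original allocation rule. The optimizer is "ranger21_style": AdamW plus the
headline Ranger21 ingredients — linear warm-up (22 % of scheduled steps),
gradient centralization on multi-axis weights, and a cosine
explore-exploit decay over the final 28 % of steps; plain AdamW is a
config switch. No early stopping; the best-validation-Dice checkpoint is
the only model selection. Augmentation is off by default; an optional
`hflip` extension mirrors images (and, for the side classifier, swaps the
LCA/RCA label, which mirroring implies).

The network stack itself (`angioseg.nn`) is a compact numpy implementation:
a tape-based reverse-mode autograd over numpy arrays, im2col + BLAS
convolutions with a fold-based backward pass, composite-autograd batch
normalization with running statistics, and the optimizers above. It is
exact but CPU-bound, which motivates the desk-scale sizes below.

## Synthetic data

The generator emulates what matters for this task and nothing more:

* vessels *darker* than background (contrast medium attenuates the beam),
  drawn as spline tubes with per-generation width taper (0.6–0.9 of the
  parent) and a smooth per-branch intensity profile emulating uneven
  contrast filling (deficit 20–60 of 255);
* trunk geometry keyed to side: the tree roots at the left (LCA) or right
  (RCA) border, descends along it and curves inward through fixed
  waypoints, so vessel mass stays on the root side; side-typical
  branching — the left main bifurcates early, the right branches in its
  distal half — mirrors LAD/LCx vs RCA morphology and keeps the side
  visually decodable. Branches are truncated 8 px before the opposite
  border so the root side is always recoverable from geometry alone;
* background = mid-gray + random tilted plane + smooth blob field
  (amplitude 30) + Gaussian noise (σ 8);
* confounders: with probability 0.3 each, a high-contrast near-straight
  catheter entering from the top edge and running past the root — present
  in the image, deliberately absent from the ground-truth mask, mirroring
  clinical labelling practice and enabling tests of the catheter-confusion
  failure mode — and one or two broad, faint, diagonal rib-like bands.

Everything is deterministic given (spec, seed). Under the default spec the
vessel fraction lies in roughly 1–5 % of pixels across seeds (the class
imbalance regime that motivates the vessel weight of 20). What the
generator does *not* emulate: projective foreshortening, cine temporal
structure, stenoses, detector blur, and real LCA/RCA anatomy beyond the
coarse cues above — so passing tests demonstrate that the pipeline learns
and routes correctly, not that it reaches clinical-grade accuracy on real
angiograms.

## Desk-scale experiment sizes

The acceptance-level learning checks run entirely on the CPU numpy stack,
so problem sizes are chosen accordingly (and stated here as the package's
own standard): segmentation uses 120 training + 30 held-out synthetic
images at 128×128 with the `tiny_z` reduced-width configuration (stem 16,
widths 16/32/48/64, decoder 48/32/24/16/12), 12 epochs, batch 4, the
default focal loss, reaching held-out Dice ≈ 0.88; the side classifier
uses 200 training + 50 held-out images at 64×64, 20 epochs, batch 8 with
the mirror augmentation, reaching held-out AUC ≈ 0.99. Both runs are
seeded and reproducible.

## Numerical choices and edge cases

* Probabilities clamped at 1e−7 before logarithms; losses are always finite.
* Convolution weight init: He-normal scaled by fan-in; BN γ = 1, β = 0.
* BatchNorm eval mode uses running statistics (momentum 0.1, unbiased
  variance); training twice with the same seed reproduces the loss history.
* Intensity dialect: 8-bit internally; float inputs rescaled through.
* Coordinates are row-major, origin top-left, 0-based (row, col); masks are
  0/255 on disk, 0/1 in memory; DCA1 ground truth binarized at > 127.
* Tile grids that do not divide the image are mirror-padded, then cropped.
* SE bottleneck width rounds up to at least 1 when the reduction does not
  divide the channel count.

## Known limitations

* The numpy backend trains small models at small resolutions in minutes but
  is far too slow for the full 512² protocol; the full-size models are
  exercised structurally (forward pass, complexity, shape algebra) rather
  than trained to convergence.
* The Z-style 4GF encoder is this package's own calibration of an
  under-specified configuration; its stage layout is plausible but not a
  reproduction of any published weight set.
* Synthetic-data performance does not transfer to clinical imagery; the
  DCA1 loader exists so that users with the public dataset can run external
  validation themselves.
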