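# Methods

This note documents the model, its tunable parameters, the synthetic data
the tests run on, and the numerical/design choices made where the design
was genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Network

BiSeNeXt is a two-branch ("bilateral") encoder for 3-class leaf/lesion
segmentation.  Input images are RGB, normalised to roughly zero mean and
unit spread (`(x/255 − 0.5)/0.25`); spatial size must be divisible by 32.

**Detail branch** (output stride 8).  Four stages of DFEB blocks with
channel widths 32/64/128/128; stages 1–3 end in a stride-2 block, stage 4
keeps resolution, and an EAMA attention sits between the stride-1 and
stride-2 blocks of each stage.  The baseline variant replaces this branch
with the original bilateral-network layout: three stages of strided 3×3
conv+BN+ReLU blocks with widths 64/64/128.

**Semantic branch** (output stride 32).  The original bilateral-network
design, kept verbatim because the method modifies only the detail branch
and decoder: a Stem (stride-4 entry, 16 channels), gather-and-expansion
layers with expansion 6 at widths 32/64/128, and a context-embedding block
(BN-ed global pooling re-injected through a 1×1 conv, then a 3×3 conv).

**Aggregation.** Bilateral guided aggregation: each branch produces a
sigmoid gate for the other after resolution alignment (bilinear up ×4 /
strided conv + average-pool down), the gated maps are summed at stride 8
and passed through a 3×3 conv.

**Booster.** Four auxiliary segmentation heads (3×3 conv to 128 channels +
1×1 classifier) on the semantic-branch stage outputs at strides 4/8/16/32,
used only for the training loss.  They are excluded from parameter totals
and FLOPs, which account for inference cost.

### DFEB

DRFConv materialises each 3×3 receptive field as 9 channels via a grouped
convolution, weights them with `Softmax(g₁ₓ₁(AvgPool₃ₓ₃(X)))` — the softmax
runs over the 9 positions of each channel group; weights sum to 1 — applies
ReLU(BN(·)) to the feature path, re-tiles the 9C×H′×W′ result
position-major into C×3H′×3W′ (one 3×3 block per slider) and collapses it
with a 3×3 stride-3 convolution.  The stride-2 variant strides both the
grouped conv and the pooling.  The stride-1 DFEB is residual
(DRFConv → 3×3 conv, 1×1 conv shortcut); the stride-2 DFEB sums a strided
DRFConv main path with a pixel-shuffle (space-to-depth, λ = 2) side path.
Odd inputs are zero-padded right/bottom once, identically for both
branches, giving ceiling semantics.

Open choices, fixed as follows: the attention's 1×1 grouped conv is
biasless; the normalisation inside DRFConv is batch norm; the shortcut 1×1
conv is always present, even when input and output widths match.

### EAMA

Channels are split into G groups folded into the batch axis; all
convolutions act on C/G channels and are shared across groups, so the
module adds only ~2.5 k parameters across the whole network.  **G = 16.**
This value is fixed by the complexity accounting: shared-conv grouping at
G = 16 is the only divisor-compatible choice that leaves the baseline's
parameter total unchanged at two-decimal precision while keeping the
attention's FLOP overhead at the sub-GMAC level the accounting reports.
The 1×1 branch output is group-normalised (one group per channel) before
cross-spatial fusion, following the attention family this module extends.
The asymmetric branch output feeds only the attention computation; the
final sigmoid map re-weights the module's *input* (attention-only, no
residual sum).

### PointRefine

Uncertainty = −|top1 − top2| of the class logits (zero gap = maximal).
Sampling draws j·N uniform candidate coordinates, scores them by bilinear
interpolation of the logits, keeps the ⌊βN⌋ most uncertain with a stable
sort (ties broken by candidate index) and tops up with fresh uniform points
to exactly N.  Coordinates are continuous in [0,1]², origin at the top-left
corner, pixel centres at ((x+0.5)/W, (y+0.5)/H), border-clamped bilinear
sampling.

The head is one fully connected layer on the 128-dim detail-branch point
feature, concatenated with the point's interpolated coarse logits, followed
by a 3×128 ReLU MLP whose output is a **residual added to the interpolated
coarse logits**; the final layer is zero-initialised, so refinement starts
as the exact identity and can only learn corrections.  Head widths (coarse
seg head 3×3 conv to 64 channels + classifier; FC 128; MLP 128) are fixed
by the published complexity accounting of the decoder variant; a 256-wide
MLP would overshoot that budget by ~80 k parameters.

Training adds one round of point sampling on the stride-8 coarse logits
with point-wise cross-entropy (weight 1.0); labels are read at the nearest
ground-truth pixel.  Inference repeats m = 2 times: upsample ×2, sample on
the current (already partially refined) map, re-label, scatter.  Sampled
points are snapped to pixel centres of the current grid before the head
runs, which makes the zero-correction case bit-exact and gives scattering a
well-defined target pixel; collisions resolve to the last point.
Fine-grained features come from the final detail-branch map (128 channels
at stride 8) — the architecture's designated carrier of spatial detail.

## Complexity accounting

Parameters: exact integer sum over eval-mode weights (booster heads
excluded).  FLOPs: one multiply-accumulate = 1 FLOP, counted for conv and
linear layers only, by instrumenting a real eval-mode forward pass at the
target size, point decoder included.  Reported as M / G rounded to two
decimals.  The full / baseline / decoder-only / DFEB-only variants are
built from one `NetworkConfig` with three switches.

## Training recipe

SGD, momentum 0.9, weight decay 5e-4, batch 8; cross-entropy on the
bilinearly upsampled main logits + booster logits + point logits, all
weights 1.0; polynomial decay `lr(t) = lr_init·(1 − t/(T−1))^0.9` floored
at `lr_min` (defaults 1e-2 → 1e-4 over 200 epochs).  Batch order and point
sampling are derived from (seed, epoch, step), so a resumed run reproduces
the original trajectory to float tolerance.  Before each validation pass
the BatchNorm running statistics are recomputed as a cumulative average
over up to six fresh training batches ("precise BN"): with few optimiser
steps per epoch the momentum-0.1 running average lags the weights badly
and eval-mode scores would understate the model.  BN: momentum 0.1,
eps 1e-5; He initialisation; align_corners=False bilinear interpolation
everywhere.

## Synthetic scenes

The generator renders the structural challenges of field photographs:
overlapping leaf-shaped blobs (radial-Fourier closed curves, painter's
occlusion order) at close-up framing — leaves fill a large fraction of the
frame, as in handheld disease photography taken tens of centimetres from
the plant — green textured over soil-textured background, irregular
dark lesion stamps inside leaves (possibly adjacent/merging; at least one
lesion per leaf whenever lesions are requested; per-leaf lesion area capped
at 60% with a warning), a linear illumination gradient, and bright
raindrop-like discs.  The mask is exact by construction.  Same spec + seed
⇒ pixel-identical scene.

What it does **not** emulate: real lesion chromatics and texture continuity
with healthy tissue, leaf venation, specular leaf curvature, camera noise
and blur, and ambiguous annotation boundaries.  Tests passing on these
scenes therefore demonstrate that the architecture, losses, decoder and
metrics are implemented coherently and that the system can learn
colour+shape segmentation end to end — not that field-data accuracy
figures transfer.

## CPU-scale experiment sizes

The end-to-end experiments run a width/8 network (channels scaled by
0.125, EAMA groups 2, N = 128 refinement points) on 200 scenes at 64×64,
split 7:2:1 and trained up to 30 epochs with lr 0.05 → 1e-4 (the default
1e-2 recipe targets the full-width 512² model; a small-width model on small
images tolerates and benefits from a larger rate).  Scene structure is kept
resolvable at the network's output stride: lesion radii are floored at 4 px
so every lesion spans at least one cell of the stride-8 logit grid, and the
close-up leaf framing means leaf interiors span many cells.  Smaller
structures are unresolvable for any stride-8 decoder and would measure the
grid, not the model.

## Augmentation and splits

Six augmentations per image, each applied once: saturation/brightness/
contrast ×U(0.6, 1.4); crop to 70–90% area (resized back); rotation
U(−30°, 30°) with reflection padding (nearest-neighbour for masks);
horizontal flip.  Originals plus augmentations give exactly 7n samples.
Splitting is stratified (by disease type, falling back to lesion presence)
with largest-remainder rounding per stratum.

## Known limitations

* The numpy backend is single-threaded and eager; training beyond toy
  scales (full-width 512² inputs) is impractical — the full-scale network
  is exercised for architecture accounting and inference, not training.
* Metrics exclude absent classes from means (with a warning) rather than
  defining 0/0 = 0; callers comparing across datasets should ensure all
  classes occur.
* The exact ×4 FLOP scaling under spatial doubling holds for conv layers;
  global-pool and directional-pool attention convs contribute constant or
  linear terms (< 0.1% of the total).
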