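# Methods

## Problem and model

`lesionmtl` implements a single network that simultaneously (i) segments the
boundary of a pigmented skin lesion in a dermoscopy-style RGB image and (ii)
classifies the lesion as benign or melanoma. The two tasks are correlated —
diagnosis depends on exactly the region the segmentation isolates — but naive
multi-task training lets one objective dominate the shared layers. The model
counters this with three coupling mechanisms: full encoder sharing,
mask-attention fusion of the segmentation output into the classifier, and a
*joint reverse connection* that feeds classification-derived channel gates
back into the final decoder levels.

### Backbone

A U-Net with six encoder blocks of widths 32, 64, 128, 256, 320, 320. Each
block is `conv3x3 (stride 2) -> BN -> ReLU -> conv3x3 (stride 1) -> BN ->
ReLU`; downsampling is by the strided convolution itself, so the stride
budget is 1/64 and input height/width must be multiples of 64 (192x256 input
gives a 3x4 bottleneck; 64x64 gives 1x1). The decoder mirrors it with five
blocks of widths 320, 256, 128, 64, 32: a 2x2 stride-2 transpose convolution,
concatenation of the same-resolution encoder map, then two stride-1
convolutions. Five mirrored blocks recover only half resolution against six
encoder strides, so a final stride-2 transpose convolution (32 -> 32, with BN
and ReLU) restores full resolution before the 1x1 convolution that produces
two-channel softmax segmentation logits. Masks are obtained by thresholding
the foreground probability at 0.5.

### Classification sub-module and the variant ladder

Classification pools features to a vector, passes them through one hidden
dense layer (128 units, ReLU), and ends in a single sigmoid melanoma logit
(decision threshold 0.5). The variant ladder adds one mechanism at a time,
and each step strictly adds parameters:

| variant | classifier input | extra mechanism |
|---|---|---|
| `seg-only` | — | pure segmentation U-Net |
| `mtl0` | GAP of the level-6 encoder map (320) | — |
| `mtl1` | + GAP of mask-attended decoder levels 4 and 5 (64 + 32) | mask attention |
| `mtl2` | + GAP of the level-5 encoder map (320) | joint reverse connection |
| `mtl3` | levels 5–6 pass through CBAM first | channel + spatial attention |

*Mask attention*: the pass-1 foreground probability map is bilinearly resized
to each decoder feature map's resolution and multiplied across its channels,
so the classifier sees lesion-focused features.

*Joint reverse connection*: the classifier's penultimate activations are
mapped by two dedicated dense layers (one per gated level) to vectors of
length 64 and 32, squashed by a sigmoid into (0,1). The last two decoder
levels are then recomputed: each gate multiplies the transpose-convolution
output of its block (which has exactly the gate's channel count) before skip
concatenation and convolution. Pass 1 supplies the classification output and
the gates; pass 2 supplies the final segmentation. Classification is not
recomputed after pass 2. Gradients flow through both passes; the gated
blocks' weights receive gradient from both the pass-1 classification path and
the pass-2 segmentation loss.

*CBAM* uses the module's customary defaults: channel attention with a shared
two-layer perceptron at reduction ratio 16 applied to average- and max-pooled
descriptors, then spatial attention with a 7x7 convolution over the
channel-wise mean and max maps. It is applied to the level-5 and level-6
encoder maps on the classification branch only.

### Losses and optimization

The objective is `L = lambda1 * L_Dice + lambda2 * L_BCE` with
`lambda1 = lambda2 = 0.5`. `L_Dice` is the soft Dice loss on the foreground
probability (smoothing epsilon 1e-5, no thresholding), averaged over the
batch; `L_BCE` is binary cross-entropy on the melanoma probability, clamped
at 1e-7 for stability. Optimization is Adam (beta1 = 0.9, beta2 = 0.999),
batch size 10, initial learning rate 0.003 decaying geometrically by one
overall decade across the run: `lr(e) = 0.003 * 10^(-e/(E-1))`. No weight
decay and no early stopping; the checkpoint with the lowest validation total
loss is kept (validation = the manifest's test split).

## Data preparation

Images are normalized per image and per channel by min–max scaling to [0,1]
(a constant channel maps to zeros — a deterministic rule for a degenerate
case), resized bilinearly (reference geometry 192x256 for real dermoscopy
data; masks are resized bilinearly and re-binarized at 0.5). The
augmentation inventory is 16 transforms: rotations by 45-degree steps
(0–315), and left-right / up-down flips composed with the four grid
rotations. Off-grid rotations use bilinear interpolation for the image,
nearest-neighbour for the mask, reflection fill, and preserve the canvas.
Class balancing expands each benign training record into the 4 grid
rotations (identity included) and each melanoma record into all 16
transforms, giving the 4x / 16x cardinalities the pipeline is designed
around (727 benign -> 2908, 173 melanoma -> 2768). The expansion is
represented as a lazy plan (record, transform-id pairs); the CLI `prep`
command materializes it to disk when wanted.

## Synthetic data generator

The generator emulates the two cues that distinguish the classes in the ABCD
dermoscopy rubric which the network can learn at desk scale:

- **Border irregularity.** Lesion boundary r(theta) = r0 * (1 + a * p(theta)),
  where p is a sum of order-2..6 sinusoids with random phases, normalized to
  unit peak, and the amplitude `a` is drawn from the class range — benign
  (0.02, 0.06), melanoma (0.25, 0.45). The ranges were calibrated once so
  that a logistic regression on (perimeter^2/4·pi·area, in-lesion colour
  variance) separates 200 generated samples at >= 95% accuracy, i.e. the
  task is provably solvable from the encoded cues; at 64x64 the discrete
  perimeter estimate compresses boundary differences, which is why the gap
  between the ranges is wide.
- **Colour heterogeneity.** Benign lesions are filled with a single pigment
  tone; melanoma lesions with >= 2 darker tones (default 3) arranged in
  smooth random patches (argmax over Gaussian-filtered noise fields).

Backgrounds are skin-toned with smooth texture and a mild gradient; dark
hair-like Bezier arcs are overlaid on half of the images when artifacts are
enabled. Lesions occupy 8–25% of the frame. Everything derives from
counter-split RNG streams, so a fixed seed reproduces every file
byte-identically.

What the generator does *not* emulate: photorealistic pigment networks,
rulers/ink markers, multi-lesion images, low-contrast lesions, or the heavy
class overlap of real dermoscopy collections. Passing the desk-scale
learning check therefore shows the architecture and training loop can learn
both tasks jointly from the intended cues — not that the model reaches
clinical performance on real data.

## Desk-scale study conditions

The end-to-end learning check (and `scripts/acceptance.py`) uses 300
synthetic 64x64 images (240 benign / 60 melanoma, split 200 train / 100 test
stratified by class), the `mtl3` variant with widths (8, 16, 32, 64, 80, 80)
— the full architecture's 1:2:4:8:10:10 width progression at a quarter of
the channel budget, sized for a single CPU — the class-balanced augmentation
policy (1280 samples per epoch), batch size 10, and 8 epochs of the decade
lr schedule. Under these conditions the held-out mean DSC exceeds 0.80 and
the weighted F1 exceeds 0.90 in at least two of three seeds; training total
loss decreases across 5-epoch windows.

## Evaluation conventions

Classification metrics come from the accumulated 2x2 confusion matrix with
melanoma positive: melanoma recall (sensitivity), benign recall (TNR,
i.e. specificity), support-weighted TPR (algebraically equal to accuracy),
and support-weighted F1 (a class with no predictions contributes F1 = 0).
These conventions reproduce, to the printed precision, every published
confusion-matrix/metric pair bundled as worked examples in the test suite.
Rounding for display is half-up at the printed precision (two decimals,
one decimal for recall quotes). Segmentation is scored per image (DSC, IOU,
MCC from pixel counts) and averaged without weights over the test set;
empty-prediction-vs-empty-truth scores DSC = IOU = 1 and MCC = 0, and MCC is
0 whenever its denominator vanishes.

## Numerical and design notes

- The network runs on a compact tape-based reverse-mode autodiff engine
  written on NumPy (float32 throughout): im2col + BLAS matmul convolutions,
  tensordot transpose convolutions, batch norm with running statistics
  (momentum 0.1, eps 1e-5), and a differentiable bilinear resize built from
  row-stochastic 1-D interpolation matrices. Max-pool gradients split ties
  evenly (a valid subgradient). Gradient correctness is verified against
  central differences in the test suite.
- Weight init is He-normal scaled by fan-in, from a seeded generator;
  training-order shuffling, synthesis, and initialization all derive from
  user-visible seeds, so runs are exactly reproducible.
- The two gated decoder levels re-run their BN layers in pass 2 with
  identical inputs under unit gates, which leaves outputs bit-identical —
  the property the unit-gate identity test checks.
- The 16-transform inventory contains the composition duplicates implied by
  dihedral-group algebra (an up-down flip plus rotation equals a left-right
  flip plus a different rotation); the policy's contract is the 4x/16x
  cardinality, not functional distinctness of all ids.
- Checkpoints are single `.npz` files embedding the architecture config, so
  `load_checkpoint` rebuilds the exact model.

## Known limitations

- CPU-only and NumPy-bound: full-width training on real datasets is out of
  reach here; the full-width architecture is exercised for shape, gating,
  and parameter-ordering properties, and training happens at desk scale.
- The classifier head's exact dense sizes are a free choice (128 hidden
  units); absolute parameter counts therefore are not a contract, only the
  strict ordering along the variant ladder.
- Binary classification only; multi-class extension would change the head,
  the gates' derivation, and every weighted metric.
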