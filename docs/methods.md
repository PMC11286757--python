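# Methods

## Model

The classifier is a convolutional network for single-cell blood-smear
images built from four stages: a convolution stem, a six-branch dilated
residual block (DRDB), a global/local feature enhancement block (GLFEB) and
a channel/spatial attention block (CSAB), followed by a fusion stage and a
small classification head. The stem output doubles as the "global" feature:
it is consumed both by the DRDB (whose output is the "local" feature) and
by the GLFEB concatenation. The CSAB output is summed elementwise with a
1×1 projection of the GLFEB local conv feature; the sum passes through
batch normalization, dropout, a final 3×3 convolution with group norm and
ReLU, global average pooling and a linear layer.

Assumptions baked into the design:

* Classes are mutually exclusive, so the default head is softmax with
  categorical cross-entropy. A per-class sigmoid head is available as a
  config switch (`head="sigmoid"`) for multi-label use; sigmoid otherwise
  appears only inside the attention gates.
* Group normalization (32 groups by default) is used inside all blocks so
  behavior is independent of batch size; batch normalization appears
  exactly once, after the fusion stage. When the group count does not
  divide a layer's channel count, the layer falls back to
  gcd(groups, channels) and logs the fallback.
* All convolutions inside the blocks are same-size padded (padding =
  dilation for dilated 3×3 kernels) so the six DRDB branches concatenate
  and the stem/DRDB features align spatially. If a configuration ever
  makes the global and local features disagree in size, the global feature
  is bilinearly resampled before concatenation.

Open design points and how they were resolved:

* The spatial-attention normalization is ambiguous for a single-channel
  map; it is implemented as a sum over all entries of the map, so the map
  is a discrete distribution over locations (sums to 1). An identically
  zero post-ReLU map cannot be normalized; those samples fall back to the
  uniform map with a logged warning (once per layer instance — trained
  models often drive the gate's convolution negative, at which point the
  spatial gate degrades gracefully to uniform weighting).
* The channel-attention stack is GAP → linear (W₁) → ReLU → two fully
  connected layers with a bottleneck (reduction ratio 8, ReLU between) →
  sigmoid. An optional dual-pool variant (`attention_dual_pool=True`) adds
  a global-max-pool path through the same weights, summing the two logits
  before the sigmoid, as in common channel-attention practice; the default
  is the single-GAP chain.
* The DRDB input is adapted by a 1×1 projection when its channel count
  differs from the branch width; the post-concatenation reduction is a 1×1
  convolution from 6×width back to width. One DRDB stage is the default;
  `drdb_depth` stacks more.
* The elementwise fusion uses the GLFEB local conv feature (pre-tanh path)
  projected to the attention output's width; batch norm and dropout follow
  the fusion, not precede it.
* Loss is categorical cross-entropy (the standard multiclass choice);
  weight decay is 0; the learning rate is constant.

## Numerical engine

All layers run on a small reverse-mode automatic-differentiation engine
over NumPy arrays (float32 throughout training). Convolution is im2col +
BLAS matmul with dilation-aware patch gathering; the input gradient at
stride 1 is itself a convolution with the flipped, channel-transposed
kernel. Max pooling routes gradients to the arg-max entry of each window
(first index on ties). `backward()` severs the recorded graph after the
pass and inference runs in a no-grad mode, so peak memory stays below
~1 GB at the scales used here. Gradient correctness is verified against
central finite differences to ~1e-9 in float64.

Other numerical choices: group/batch norm epsilon 1e-5; softmax and
cross-entropy use the max-subtraction log-sum-exp form; He-uniform
initialization for convolutions and linear layers, unit gamma / zero beta
for normalization layers; Adam with β = (0.9, 0.999), ε = 1e-8; prediction
ties break to the lowest class index; the best checkpoint maximizes
validation accuracy with lower validation loss as the tiebreak (training
metrics stand in when no validation split exists).

## Augmentation

Four transforms on [0, 1] float images, 0-based (row, col) coordinates:
horizontal flip (`out[i, j] = in[i, W−1−j]`); rotation, default 10°
clockwise, bilinear, zero fill, about the image center (the bare
coordinate-rotation form about the origin is also exposed); zoom, default
scale 2, center-anchored bilinear by default with the top-left-anchored
nearest-neighbour index form `out[m, n] = in(⌊m/s⌋, ⌊n/s⌋)` as an option;
and mean-anchored contrast stretch `clip((x − mean)·f + mean, 0, 1)` with
f drawn uniformly from (0.7, 1.3) — the stretch factor range is a package
choice, as is the zero rotation fill. Cropping is deliberately excluded.

Class balancing composes these transforms on originals (each enabled
transform included with probability ½, rotation sign random, identity
compositions resampled), keeps every original, and rejects byte-duplicate
candidates for up to 20 redraws so small transform groups are enumerated
before any duplicate appears. Balancing refuses sets spanning more than
one split: splitting precedes augmentation, so augmented copies never leak
across train/test.

## Synthetic data

The generator draws one cell per image on a stain-tinted noisy background:
cytoplasm as a smoothed ellipse (jittered center, radius ≈ 30% of the
canvas), nucleus per class — 3–5 lobes (neutrophil), an indented kidney
ellipse (monocyte), two lobes plus Poisson-scattered red granules
(eosinophil), or a single nucleus filling 72–85% of the cell area
(lymphocyte) — followed by a light Gaussian blur and pixel noise
(σ = 0.03). Every image records the ground-truth cell bounding box, which
the Grad-CAM localization check consumes. Generation is a single seeded
generator stream, hence byte-reproducible.

These images emulate the morphology cues that distinguish the classes.
They do **not** emulate stain variability, focus blur, touching or
overlapping cells, debris, or class-imbalanced acquisition — so passing
tests demonstrate that the implementation can learn and localize the
intended morphological signal, not that the model reaches any particular
accuracy on real smears.

A deliberately simple check guards learnability: hand-crafted features
(nucleus lobe count, nucleus/cell area ratio, granule fraction) feed a
linear classifier that must exceed 80% held-out accuracy on generated
images.

## Study scales

Learning checks run at a desk scale chosen once: canvas 56 px and a
width-reduced configuration (stem 8, branch width 8, GLFEB 8/16/8, 4
normalization groups, head width 8; ~13 K parameters) with the published
recipe otherwise unchanged (Adam, lr 0.01 constant, dropout 0.2). Under
these conditions the model overfits 40 images (10 per class) to 100%
training accuracy within 50 epochs and reaches ≥ 90% test accuracy on a
400-image 80:20 split after 15 epochs. The full-size configuration
(224 px, stem 32, branch 64) is instantiated for shape and
parameter-count checks; its parameter count (~0.77 M) is compared against
an 18-layer residual reference (~11.2 M) built with the same layer
primitives and torchvision's layout conventions (bias-free convolutions,
2-2-2-2 basic blocks).

The ablation harness trains seven block subsets (stem, stem+DRDB,
stem+DRDB+CSAB, stem+GLFEB, stem+GLFEB+CSAB, stem+DRDB+GLFEB, full) on
identical splits and seeds. Parameter counts are asserted to increase
strictly along the nested chain stem ⊂ stem+DRDB ⊂ stem+DRDB+GLFEB ⊂ full;
the sibling variants are not totally ordered by size (a DRDB at the
default widths outweighs a GLFEB), so no ordering is claimed between them
beyond containment in the full model.

## Known limitations

* The engine is single-threaded NumPy; it is meant for desk-scale
  experiments and correctness work, not GPU-scale training.
* Benchmark-scale results on public blood-cell datasets require those
  datasets and longer training; the package reads any directory-per-class
  JPEG/PNG tree for that purpose but ships no downloader.
* Grad-CAM is implemented in its canonical gradient-GAP form only; no
  Grad-CAM++ or score-CAM variants.
* The synthetic generator's class separability is by construction higher
  than real smears; accuracy numbers on it are upper bounds of convenience,
  not clinical estimates.
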