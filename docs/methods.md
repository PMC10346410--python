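# Methods

`branchmorph` measures branch phenotypes — per-branch length and
inclination angle — from RGB images of tall trees, in two stages: a
semantic segmentation model that separates background, trunk and branch
pixels, and a skeleton-based morphometry pipeline that turns each
segmented branch into a (length, angle) record. A synthetic scene
generator provides paired imagery and exact ground truth for testing
every stage. This note records the models, the parameter choices, and
the numerical decisions behind them.

## Segmentation model

The network is a UNet with a VGG16-style encoder: thirteen 3×3
convolutions in blocks of [2, 2, 3, 3, 3] (ReLU after each), a
2×2/stride-2 max pool after each of the first four blocks, and channel
widths (c, 2c, 4c, 8c, 8c) for a base width `c`. The decoder mirrors
the encoder with four 2×2 transpose-convolution upsampling stages, each
concatenating the matching encoder skip tensor and refining with two
3×3 convolutions; a 1×1 convolution plus softmax yields per-pixel
probabilities over {background, trunk, branch}. Output height/width
always equal the input's; inputs not divisible by 16 are reflect-padded
and the output cropped back.

Two attention mechanisms augment the UNet:

* **Squeeze-and-excitation (SE).** Each channel m of a feature map u is
  squeezed to its spatial mean z_m = (1/wh) Σ_ij u_m(i,j); the vector z
  passes through a two-layer bottleneck s = σ(W₂ · ReLU(W₁ · z)) with
  reduction ratio r (W₁: c/r×c, W₂: c×c/r, σ the logistic function);
  channels are rescaled as x̃_m = s_m · u_m. SE modules sit before each
  of the four encoder pools and at five decoding-path sites: the
  bottleneck plus each post-concatenation tensor. The five-site reading
  is one of several consistent placements for a four-stage decoder; it
  is exposed in `UNetConfig` (`decoder_se`) rather than hard-coded.
* **Residual attention module (RAM).** The input x is convolved and
  ReLU-activated into f. Channel attention pools f to its per-channel
  *population variance* over spatial positions (variance rather than
  mean pooling, emphasizing detail-rich channels); spatial attention
  applies a depthwise 3×3 convolution to f. The c×1×1 and c×h×w maps
  are broadcast-summed — the only shape-consistent fusion — gated by a
  sigmoid, multiplied with a second, independently parameterized 3×3
  convolution of f, and added back onto x. With all weights zero the
  block is exactly the identity, which the tests assert. RAM sits after
  the first encoder SE site, before the first pool.

Defaults: `base_channels=64`, `se_reduction=16` (the standard ratio in
the channel-attention literature; any value dividing all channel widths
is accepted), `ram_kernel=3`. Weights are He-initialized; no pretrained
backbone is bundled, keeping the package self-contained and runs
exactly reproducible.

### Training

Pixelwise cross-entropy, Adam, initial learning rate 1e-4 decayed by a
half-cosine lr(t) = lr₀ · ½(1 + cos(πt/E)), batch size 4, E = 300
epochs, with the 13-convolution backbone frozen for the first 150
epochs and then released — the two-phase fine-tuning schedule the model
is intended to be trained under on real imagery. All of these are
`TrainConfig` fields.

The numeric core is a small NumPy layer library with hand-written
gradients (`branchmorph.nn`), checked against central differences in
the test suite. This keeps the package dependency-light and makes
training bitwise-reproducible on CPU for a fixed seed — the loss
history is part of the deterministic contract. The cost is speed: the
full-width network is impractical to train here, so tests and the
acceptance script run a proportionally scaled configuration
(`base_channels=8`, `se_reduction=4`, 128×128 scenes, 4–9 training
images, 50–100 epochs, lr 3e-3 without a freeze phase — an overfitting
sanity regime, not a field-training recipe). These sizes are the
package's own choice of a desk-scale experiment; they exercise every
architectural component at realistic depth while a full run remains a
matter of configuration, not code.

## Thinning

Branch skeletons come from the classical two-subiteration parallel
thinning algorithm. With the eight neighbors of a pixel P1 labelled
P2..P9 clockwise from north, a foreground pixel is deleted when its
neighbor count N(P1) ∈ [2, 6], its cyclic 0→1 transition count S(P1)
equals 1, and the directional products (P2·P4·P6 = 0 ∧ P4·P6·P8 = 0 in
sub-iteration one; P2·P4·P8 = 0 ∧ P2·P6·P8 = 0 in sub-iteration two)
vanish. Deletion within a sub-iteration is simultaneous
(mark-then-delete, the canonical parallel formulation); the image is
implicitly zero-padded so border windows are defined; iteration stops
when a full round deletes nothing. The result is always a subset of the
input and a fixpoint of the operator, and no 8-connected component ever
splits or merges (tested on random blobs; see the known limitations for
the one topological caveat, whole-component annihilation).

Two code paths exist: a vectorized kernel used by the pipeline and a
literal per-pixel transcription kept as a cross-check; the test suite
holds them equal on thousands of random grids, against a third,
independently written oracle. Note that `skimage.morphology.skeletonize
(method="zhang")` is *not* equivalent: it also deletes corner pixels
with S(P1) = 2, which the rules above retain, so it cannot serve as a
drop-in reference for this operator.

## Morphometry

Given a class mask, each non-background class is split into 8-connected
components (8-connectivity so thin diagonal branches do not fragment).
Components below `min_area` pixels (default 50, configurable) are
discarded as segmentation noise; the survivors are relabelled
sequentially ordered by (class, top-left pixel), which makes record
order deterministic. Overlapping branches of the same class form one
component and are deliberately measured as a single target — a 2-D
image cannot disambiguate them.

Each instance is thinned and its **length** reported as the skeleton
pixel count. Its **inclination** comes from a straight-line fit to the
skeleton pixels minimizing the summed squared orthogonal (Euclidean)
distances — total least squares, solved in closed form as the principal
eigenvector of the coordinate scatter matrix. (An L1 orthogonal fit has
no closed form; the squared-distance fit is the standard, unique
choice.) The angle is the arctangent of the axis direction measured
from the horizontal image axis with y up, reported in [0, 180): 0° is
horizontal, 90° vertical, values above 90° lean left. This range keeps
one value per undirected line while distinguishing left- from
right-leaning branches; trunk instances are measured by the same rule
as branches. Isotropic pixel sets (no unique principal axis, e.g. a
square blob) are flagged degenerate and reported with NaN angle rather
than aborting a batch.

## Synthetic scenes

`branchmorph.synthetic` renders tree-like scenes with exact ground
truth: one thick near-vertical trunk stroke (width 9–14 px) and 2–5
thinner branch strokes (default widths 2–8 px, axis lengths 40–140 px,
angles 5–175°) over a textured background with optional elliptical
clutter blobs and Gaussian pixel noise (σ = 4 by default). Strokes are
placed mutually disjoint with a guard gap so ground-truth records map
one-to-one onto measured instances.

A stroke is rasterized without anti-aliasing as a Bresenham axis whose
endpoint is chosen so the axis has exactly the requested pixel count,
dilated by a **square** footprint of the requested width. The square
(rather than round) footprint matters: a round footprint swept along a
digital line leaves periodic bumps on the stroke boundary, and the
thinning rules convert each bump into retained staircase corners
(S(P1) = 2) that inflate the skeleton count by up to ~40% near 30°/60°
strokes. With square footprints the stroke boundary is itself a digital
straight line at every angle, and the skeleton count recovers the axis
pixel count to within a few percent across all widths and angles — this
is what makes the rendered axis length an honest ground truth for the
length measurement.

Condition tags emulate acquisition weather photometrically — sunny /
rainy / night / snowy adjust palette, brightness and noise; foggy
collapses contrast toward haze; typhoon applies a horizontal motion
streak (wind shake during exposure). Perturbations touch only the RGB
render, never the class mask or the ground truth, so one geometric
scene can be re-rendered across conditions. The generator makes no
attempt at photorealism: no foliage, occlusion, perspective or
background branches. Passing tests therefore demonstrate the
correctness of the machinery — segmentation contracts, skeleton
geometry, metric arithmetic — not field-grade segmentation accuracy on
real imagery, which depends on training data the package does not ship.

## Evaluation metrics

From a (K+1)×(K+1) pixel confusion matrix: IoU_i = TP_i/(TP_i + FP_i +
FN_i), MIoU the unweighted class mean (background included), precision
and recall averaged over classes (macro by default; a
frequency-weighted mode is provided since either reading of a
multi-class average is defensible), and F1 the harmonic mean of the two
reported averages. Classes absent from both truth and prediction have
undefined ratios; they contribute 0 with a `RuntimeWarning` so
degenerate masks stay scoreable without silently inflating scores.
Measurement agreement uses R² = 1 − Σ(tᵢ−mᵢ)²/Σ(tᵢ−t̄)² and RMSE =
√(mean (tᵢ−mᵢ)²); R² is NaN (flagged) for constant reference values.

## Known limitations

* Lengths and angles are reported in pixels/degrees in the image plane;
  no metric calibration or 3-D disambiguation is attempted.
* The thinning operator's staircase behavior on bumpy region boundaries
  (see above) means skeleton pixel counts on *real* segmentation masks
  carry an angle-dependent bias that the synthetic benchmark, with its
  grid-aligned stroke edges, does not exhibit.
* The NumPy training core is single-threaded per operation and suited
  to small experiments; large-scale training would normally be ported
  to a GPU framework while keeping this package's reference semantics.
* The literal two-subiteration thinning scheme is known to *annihilate*
  certain shapes outright rather than reduce them to a point: a 2×2
  square, and any shape whose erosion passes through one (including
  even-length two-pixel diagonal ribbons), thins to the empty set. The
  surviving skeleton never splits or merges components — the property
  the tests assert — but a count-preservation claim would be false for
  such pathological inputs. Elongated stroke-like regions, the shapes
  this package measures, are unaffected.
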