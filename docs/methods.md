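# Methods

## Model

One training image `x_i` yields three views.

**Prior view `v_p`.** The image is converted sRGB → CIELAB (D65, via
scikit-image) and the argmax of the a\* channel is taken as the
suspected-pathology location; ties break to the first pixel in
row-major order, and a constant image therefore returns (0, 0). A
square crop of side `crop_side` (default 48 px on 128-px scenes,
analogous to the 100–150-px crops used on 336–576-px real frames) is
centred there, *clamped* — not padded — to stay inside the image, so no
synthetic black borders enter the redness statistics. The crop is
resized to 120×120 and transformed with a draw from `T_p`. No smoothing
is applied before the argmax by default (`presmooth_sigma = 0`): the
prior is defined by the single reddest pixel, and the generator
guarantees the lesion contains it.

**Distorted view `v_d`.** The image is partitioned into a 3×3 grid
(cell edges at `round(i·N/3)`). A tile is *shared* when its pixel
intersection with the prior box is nonempty (an overlap-fraction
threshold is exposed in config; 0 is the default). Shared tiles are
transformed with draws from `T_p` — the same distribution as the prior
view, which is what makes the mutual content consistent between views —
non-shared tiles with the degrading set `T_d`. Tiles are resized to
40×40, shuffled by a uniform random permutation (recorded in the
bundle), and encoded in shuffled order.

**WIN view `v_win`.** The prior-box region is zeroed in all channels,
the masked image is resized to 120×120 and transformed with `T_win`. A
prior box covering the whole image degenerates to an all-zero view and
raises a warning.

**Transform sets.** The operator lists are a design choice of this
package: `T_p` = horizontal/vertical flips, axis-aligned rotations,
±10% brightness/contrast/saturation jitter, random resized crop with
scale 0.8–1.0; `T_d` = Gaussian blur (σ ∈ [1, 3]), ±40% colour jitter,
grayscale with probability 0.3, 30%-side cutout; `T_win` = flips plus
±10% jitter. `T_p` is chosen to preserve pathology appearance, `T_d` to
degrade non-mutual content, and all three are overridable in the YAML
config (`transforms.{T_p,T_d,T_win}`). Every operator maps float RGB in
[0, 1] to the same shape and range and draws all parameters from a
generator derived from the view seed, so bundles are bit-reproducible.

## Encoder

`tiny_cnn` is four 3×3-conv blocks (16, 32, 64, 128 channels), each
stride 2 with batch normalisation and ReLU, followed by global average
pooling — about 100k parameters, a forward pass on a 120×120 input in a
few milliseconds on one CPU core. A 128-d fully-connected head and L2
normalisation produce `z_p` (and `z_win`). For `v_d`, each tile passes
through the (shared, by default) trunk and a tile head to 128-d; the
nine codes are concatenated in their permuted order and compressed by
one fully-connected layer to 128-d, then normalised. `share_trunk =
false` instantiates a fully separate tile trunk for users who want the
two-encoder reading of the architecture. A `resnet50_like` deeper trunk
is available in config for larger runs; the tests exercise `tiny_cnn`.

The batch normalisation is load-bearing, not cosmetic: pooled ReLU
features of *unrelated* images share a dominant per-channel activation
profile, so without per-channel centring all unit-normalised codes
start out with pairwise cosines ≈ 0.999 and the contrastive gradients
(∝ score differences / τ) are too small to escape the collapsed
configuration. Train mode uses batch statistics; evaluation and
snapshot encoding use EMA running statistics (momentum 0.1).

Everything runs on a minimal reverse-mode autograd engine over numpy
(`priorcon.autograd`): im2col convolution, batch/layer norm, log-sum-exp
and the score ops, with gradients verified against central differences
in the test suite. Training arrays are float32; the numpy loss/metric
functions used by tests and analyses compute in float64.

## Objectives and memory bank

The bank holds one unit-norm row per training image, initialised i.i.d.
uniformly on the sphere (in 128-d random rows are nearly orthogonal, so
early negatives are uninformative but harmless). Per step the rows of
the current batch are updated as
`R_i ← normalize(m·R_i + (1−m)·z_p_i)` **after** the SGD step, so the
positive used in the loss is always the stale pre-update row; the EMA
momentum `m` is not stated by the method's description and defaults to
0.5 here, the value of the memory-bank lineage it builds on.

Negatives for the two loss terms are drawn independently, k per term
(2k per step), uniformly without replacement from the bank excluding
the anchor's own row. WINCon appends the batch's WIN codes to both
terms' negative lists; an instance's *own* WIN code is included, which
is the literal reading of the formulation — excluding it is possible
via the PGCon escape hatch but not default. Scores are cosine
similarities over τ = 0.07; every softmax is evaluated with a
max-shifted log-sum-exp since exponents reach 1/τ ≈ 14.3. The batch
loss is the arithmetic mean over anchors.

## Training

Mini-batch SGD, cosine-annealed learning rate from 0.012 to 1.2×10⁻⁵
stepped per iteration, batch 64, k = 200 and 600 epochs at full scale
(these are the config defaults); SGD momentum (0.9) and weight decay
(10⁻⁴) are not stated at the source and are set to the lineage's
conventional values, all overridable. One master seed fans out through
stable hashing to per-component child seeds (scenes, per-epoch view
transforms, bank init, negative draws, batch order), which makes
training-log CSVs byte-identical across reruns. Snapshot epochs dump
deterministic (transform-free) `z_p`, `z_d`, WIN codes and the bank
rows to CSV for the embedding analyses. A `pirl-baseline` objective
replaces the prior crop with a random crop and disables WIN, as a
comparison harness.

## Evaluation protocols

**Zero-shot weighted kNN.** Reference codes are deterministic prior
views of the labelled pretraining split; queries come from a disjoint
held-out set. Each query's top-k cosine neighbours vote with weight
`exp(s/τ_knn)`, τ_knn = 0.1, k = 290 capped at `n_train − 1` (desk-scale
reference sets are far smaller than 290); ties go to the lowest class in
sorted order. No parameters are updated anywhere (asserted by
checksumming the checkpoint).

**Linear probe.** Features are extracted once from the frozen encoder;
a two-layer fully-connected head (128 hidden units) is trained with
full-batch SGD on the softmax cross-entropy.

**Alignment / uniformity.** `L_align = E‖z_a − z_b‖^α` over positive
pairs with α = 2, where a positive pair is (z_p, z_d) of the same image
— the pair the view term aligns; `L_uniform = log E exp(−t‖z_i − z_j‖²)`
over all distinct pairs with t = 2. The exponents α and t are the
metric's standard defaults and are config-exposed. For reference, 2000
i.i.d. uniform unit vectors in 128-d give L_uniform ≈ −3.938, not −4:
the finite-dimension correction `log E[e^{4·cosθ}] ≈ 4/(2·128)·4 =
0.0625` is visible at d = 128.

**PCA evolution.** A 2-component PCA is fitted per snapshot over the
union of the z_p / z_d / GN (bank) / WIN groups; coordinates are emitted
per group for plotting how WIN codes migrate away from prior codes as
training progresses. The summary statistic used in tests is the mean
cosine between each image's z_p and its own WIN code, compared between
the first and last snapshots.

## Synthetic scenes

Each scene is a pure function of its `SceneSpec` (seed included).
Background: Gaussian noise smoothed at `texture_scale` (8 px), mapped
into a pink-tan sRGB gamut. Nuisance factors are *chroma-reducing by
construction* — bubbles and speculars push pixels toward white, the
illumination ramp is purely multiplicative — so they can never
out-redden a lesion; this is what makes the redness-dominance property
(a\*-argmax inside the lesion mask, measured at 100% over 200 default
scenes) hold by design rather than by luck. The three phenotypes
differ in shape and chroma: a compact red disc, a pale yellowish bump
with a shaded rim, and a thin curved reddish streak. Each class also
carries a mild global tone shift (inflamed frames redder overall,
pale-lesion frames paler), mirroring how pathology co-occurs with
globally shifted mucosal appearance; without some global class signal,
lesions at random positions on independent backgrounds are
information-theoretically invisible to mean pixel-space distances.

What the generator does **not** emulate: real optics (vignetting,
motion blur, compression), fluid dynamics, anatomy-dependent texture
families, class-imbalanced long-tail pathology distributions, or
inter-frame correlation of video. Passing tests on these scenes
demonstrate that the pipeline's machinery behaves as specified — the
prior finds what it is defined to find, the objectives optimise what
they are defined to optimise — not that the method reaches any
particular accuracy on real capsule data.

## Desk-scale protocol sizes

The benchmark protocol pretrains on 90 scenes (30 per class), batch 16,
k = 32 negatives per term, 20 epochs, and evaluates zero-shot on 45
held-out scenes; these sizes keep a full run to roughly a minute per
seed on one CPU core while leaving the task learnable but not trivial.
The full-scale defaults (batch 64, k = 200, 600 epochs, ResNet-style
trunk) remain available through configuration.

## Known limitations

- The prior is colour-based; pathologies with no redness signature are
  only found via the global-tone and shape cues the generator adds.
- The autograd engine is minimal by design: no GPU, no mixed precision,
  single-threaded; paper-scale pretraining is a configuration, not a
  tested regime.
- Batch-norm batch statistics couple instances within a step, so codes
  computed during training differ slightly from eval-mode codes; all
  reported metrics use eval mode.
- `L_uniform` on small snapshot sets is a noisy statistic; compare runs
  only at matched problem sizes.
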