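# Methods

This note documents the models, conventions and design choices behind
`hypomil`, in the spirit of a methods appendix: what is computed, under
which assumptions, which knobs matter, and what the synthetic experiments
do and do not demonstrate.

## Weak-label stratification

The hypoxia score of sample *k* is the median-split metagene sum over a
signature gene set: each gene contributes +1 if the sample's expression is
*strictly above* the cohort median for that gene, else −1. Ties therefore
count as "not above" — a deterministic convention that matters only for
discrete or constant expression values. With G genes the score lies in
[−G, G] and has the parity of G. Samples with score > 0 are hypoxic; the
hypoxic group is subdivided at score 20 into low (0 < s ≤ 20) and high
(s > 20) strata. The signature is an input (any gene list present in the
matrix); nothing is hard-coded. The scorer is a scikit-learn transformer:
`fit` learns cohort medians, `transform` scores samples against them, so a
held-out sample is scored against the training cohort's medians.

Cohort splitting draws independent seeded 75/25 splits (three by default),
stratified by the binary label. Stratification is a robustness choice at
small cohort sizes: it prevents degenerate test sets with a single class.

## Preprocessing

Slides are cut into a non-overlapping grid of square tiles (256 px
default); partial edge tiles are dropped. Tissue segmentation is per tile:
the tile is converted to grayscale with standard luminance weights
(0.2125/0.7154/0.0721), an Otsu threshold is computed on the tile's own
histogram, and pixels strictly below the threshold count as tissue. A
constant-intensity tile has no Otsu threshold; it is flagged and assigned
fraction 0. Tiles are kept when their tissue fraction *strictly exceeds*
the cutoff (default 0.5) — the boundary case of exactly 50 % tissue is
discarded.

Training augmentation applies, each with independent probability 0.5:
rotation by a random multiple of 90° (avoiding interpolation), horizontal
and vertical flips, hue shift uniform in ±0.05 (fractional hue), gamma in
[0.8, 1.25], and additive Gaussian noise with σ = 5 gray levels. The
magnitudes are mild and label-preserving.

## The MIL model

Tiles are scaled to [0, 1] per channel; a convolutional encoder produces a
spatial feature map, global average pooling reduces it to one value per
channel, and a linear projection maps the channel count to the fixed
512-feature tile embedding (the projection is skipped when the encoder
already ends at 512 channels, as the VGG-19-style stack does). Two
encoders are provided:

* `small_cnn`: a 2× average-pool stem followed by three stride-2 3×3 conv
  blocks (8/16/32 channels, ReLU). It exists so that the full pipeline
  trains in minutes on one CPU; it is the encoder used by the tests.
* `vgg19_like`: the 16-conv-layer VGG-19 feature stack, randomly
  initialised. No pretrained weights are bundled; at full scale one would
  initialise from ImageNet weights.

Convolutions use edge-replicate padding, so a spatially constant tile stays
constant through the stack — this keeps class-activation maps of featureless
tiles flat instead of ringing at the borders.

Bag aggregation is either the element-wise maximum over tiles or gated
attention pooling: per-tile scores wᵀ(tanh(V f) ⊙ σ(U f)) (hidden width 64
by default), softmax-normalised over the bag into a convex combination.
Attention weights are exposed for reporting. Both poolings are invariant
to tile order; max pooling is additionally invariant to duplicating tiles,
attention to duplicating the whole bag.

**Classification head.** The pooled bag feature is rectified, then mapped
through a dense layer to two logits and a softmax:
softmax(relu(Pool(·)) · W₁ + b₁). The alternative reading — rectifying the
two logits *after* the dense layer — has a training dead zone: once SGD
pushes both logits negative (which happens within an epoch at any usable
learning rate on desk-scale data), the rectifier blocks every gradient and
the model is permanently stuck at p = (0.5, 0.5). The rectify-then-dense
placement is mathematically adjacent, has no dead zone, and is the one
implemented; the decision is isolated in `_MILNet.logits`.

**Training.** Plain SGD (no momentum), one bag per step, cross-entropy
loss. The published schedule (lr 3·10⁻⁴, 100 epochs, bag size 20) is the
`ModelConfig` default; the desk-scale experiments in this repository use
lr 0.01 and 15–30 epochs, chosen as the package's own short schedule for a
randomly initialised small encoder. Each epoch redraws a fresh bag of 20
tiles per sample (without replacement when the sample has enough tiles,
with replacement otherwise). A fixed `random_state` makes initialisation,
bag resampling and hence the whole loss history reproducible. At
inference, all of a sample's filtered tiles form the bag; a sample with
zero surviving tiles is treated as unevaluable, never silently scored.

The network runs on a small reverse-mode autodiff engine written on numpy
(`hypomil.autograd`): broadcast arithmetic, matmul, the pointwise
nonlinearities, reductions, softmax/cross-entropy, im2col-based
convolution, and the pooling operators. Every operator's gradient, and the
end-to-end loss gradient of both pooling variants, is checked against
central finite differences in float64 in the test suite. Production mode
is float32. Sub-gradient conventions: the bag max routes its gradient to
the first arg-max tile per feature; spatial max pooling splits ties evenly.

**Explanation.** Class-activation maps are gradient-weighted: the winning
class's score is backpropagated to the last conv feature map, gradients
are averaged spatially into channel weights, the weighted activation sum
is rectified, scaled by its maximum into [0, 1] (an all-zero map stays
zero), and bilinearly upsampled to tile size.

## Evaluation

Per split, AUROC, accuracy, precision and recall are computed on the test
samples for three comparisons: all hypoxic vs normoxic, low-stratum
hypoxic vs normoxic, and high-stratum hypoxic vs normoxic; results are
averaged over the splits with SD. A stratum with a single class in some
split is reported as undefined for that split and excluded from the
average. AUROC uses the rank/trapezoidal convention (scikit-learn).

**Permutation null.** The planted-signal experiment is accompanied by a
label-permutation control in the standard form: cohort labels are permuted
as a whole, the model trains on the permuted training labels, and its
predictions are scored against the permuted *test* labels, averaged over
the three splits. Scoring a permuted-label model against the true labels
is degenerate on strongly separable synthetic data: the null model's
decision axis always retains a residual texture component of arbitrary
sign, and because texture orders the classes perfectly, that AUROC lands
near 0 or 1 rather than 0.5. Against permuted test labels — noise with
respect to anything learnable — the null concentrates at chance.

## Morphometrics

GLCM texture: tiles are converted to 8-bit grayscale (256 gray levels, no
requantisation); the co-occurrence matrix is accumulated at distance 1 for
angles 0°, 45°, 90°, 135°, counting pairs in one direction per angle
(offset (round(d sinθ), round(d cosθ)), symmetric = false, normalised to
sum 1). Homogeneity, energy and correlation (plus contrast and
dissimilarity as extras) are computed from P by direct weighted sums and
averaged over the four angles. On a constant tile the marginal variances
vanish and correlation is undefined: it is returned as NaN with a flag and
excluded from group statistics, never imputed.

Shape: masks must be single connected components of ≥ 8 pixels. Axis
lengths use the normalized-second-central-moment ellipse convention;
eccentricity is √(1 − b²/a²); "diameter" is the equivalent (area-derived)
diameter √(4·Area/π); extent is area over bounding-box area; solidity is
area over convex-hull area. The perimeter uses the Crofton projection
estimator: measured on rasterized disks (r = 10–30), it gives circularity
0.995–1.008, whereas the weighted boundary-step estimator drifts to
0.93–0.95, so Crofton is the estimator consistent with "a perfect circle
has circularity 1".

**High-confidence tile selection.** Tiles are scored as bags of one
instance; a tile is retained for its arg-max class when the winning
probability strictly exceeds the cutoff (default 0.9, appropriate for
fully trained, calibrated models). Briefly trained desk-scale models rank
tiles well but compress probabilities into a band of width ~0.01 around a
small constant offset — a domain shift between bags of 20 and bags of one
— which sends every tile to the same class under absolute thresholds. An
explicit opt-in `calibration="median"` recenters the cohort's median tile
score at 0.5 before the argmax/cutoff semantics; for a calibrated model
this is a near no-op. Tile-level analyses prefer the attention-pooled
model, whose convex-combination bag feature keeps single-tile scoring in
distribution (measured tile-ranking AUROC ~0.95 vs ~0.79 for max pooling
at desk scale).

## Group comparisons and reporting

Feature differences between called-hypoxic and called-normoxic groups use
a two-sided Mann–Whitney U test (nonparametric, matching the box-plot
presentation of skewed morphometric features); Welch's t is available
behind a flag. Stars follow the conventional ladder (∗ p<0.05, ∗∗ p<0.01,
∗∗∗ p<0.001, ∗∗∗∗ p<0.0001). P-values are raw and per-feature; no
multiple-testing correction is applied, which is a caveat when many
features are screened. Box-plot summaries (quartiles, whiskers at
1.5·IQR clipped to the data range) are exported alongside. Groups with
fewer than three finite values are skipped with a warning.

The pipeline driver seeds every stage from one seed and writes a manifest
with the full configuration and a SHA-256 hash of every output, so a rerun
is verifiably byte-identical.

## The synthetic cohort

The generator emulates the statistical structure the analysis needs, not
histology itself:

* **Slides** are a near-white background (gray ≈ 245) with a central
  tissue disc (55 % of the frame) rendered as Gaussian-smoothed noise in
  an eosin-like pink; the blur sigma (`texture_granularity`, default 1.5 px
  normoxic vs 5.0 px hypoxic) sets the texture correlation length and is
  the planted class signal the CNN must find. The noise field is
  renormalised after smoothing so only the correlation length, not the
  variance, differs between classes.
* **Bright lumen/vacuole speckle** (~10 % of tissue area at background
  brightness) gives every fully-tissue tile a bright minority mode. This
  mirrors lumina and fat in real H&E and is what makes *per-tile* Otsu
  behave: without a bright mode, Otsu splits the tissue's own noise and
  every interior tile hovers at 50 % tissue. Nucleus/cytoplasm contrast
  is kept moderate so Otsu separates bright-vs-tissue rather than
  nuclei-vs-cytoplasm.
* **Nuclei** are darker purple ellipses with per-class, per-cell-type
  (major, minor) axis lengths (hypoxic epithelial default 22 × 11 px,
  i.e. axis ratio 2 vs round normoxic nuclei). Centers snap to the pixel
  grid: an off-grid circle rasterizes with broken 4-fold symmetry and
  acquires a spurious moment eccentricity of ~0.1 that does not decay
  with size, whereas grid-centered circles measure exactly 0.
* **Per-slide stain jitter** (multiplicative gain, sd 0.04, and
  per-channel offsets, sd 4 gray levels) models slide-to-slide staining
  and illumination variation. Besides realism, it supplies sample-level,
  class-independent variation — the features an honest label-permuted
  model should latch onto.
* **Expression** is log-normal per gene (log2 values N(μ_g, 0.5), μ_g
  uniform in [3, 8]); the 52 signature genes gain `signature_shift`
  (default 2.5 log2 units = 5 within-class SDs) in hypoxic samples;
  background genes are exchangeable between classes. The exact noise
  family is irrelevant to the median-split score.
* **Annotated tiles** are MoNuSaC-like: class-textured tiles with
  non-overlapping rendered nuclei whose exact pixel masks are returned as
  annotations (16-bit labelled PNG plus a CSV index on disk, rather than
  a polygon dialect).

All outputs are pure functions of the configuration: every artifact draws
from its own `numpy` substream derived from (seed, stream, index).

**What passing tests show — and don't.** The synthetic cohort demonstrates
that the implementation recovers planted texture, shape and expression
signal end-to-end, that the weak-label machinery, pooling invariances and
morphometric formulas are correct, and that results are reproducible. It
does not demonstrate clinical validity: real H&E tissue has structured
morphology (glands, stroma, lymphocytes), staining artifacts, and far
weaker, spatially heterogeneous hypoxia signal than the planted one; the
published full-scale setting (≈1000 WSIs, pretrained VGG-19) is outside
desk scale and out of scope here.

## Problem sizes and defaults

The test experiment uses 40 samples per class on 1024 × 1024 px slides
(16 tiles each, ~11 surviving the tissue filter), the small encoder, bag
size 20, lr 0.01, 15 epochs for the three max-pool splits and 30 epochs
for the attention model used in tile-level analyses; the demo config in
`examples/demo.yaml` uses 16 samples per class. These sizes were chosen as
the package's desk-scale study conditions; the published full-scale
schedule (lr 3·10⁻⁴, 100 epochs) remains the `ModelConfig` default.

## Known limitations

* The `vgg19_like` encoder ships without pretrained weights; training it
  from scratch at desk scale is not useful, and it is only smoke-tested.
* Desk-scale models are weakly calibrated; absolute probability cutoffs
  (0.9) are only meaningful after long training on rich data, hence the
  documented median recentering for tile-level work.
* With the default 5-SD signature shift, scores are extreme and the low
  stratum (0 < score ≤ 20) is usually empty in small synthetic cohorts;
  its metrics are then reported as undefined rather than fabricated.
* No stain normalisation, color deconvolution, or pyramidal WSI-format
  handling; slides are plain raster images.
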