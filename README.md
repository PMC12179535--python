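# hypomil

Weakly supervised detection of hypoxia-associated morphology in H&E
histology, with downstream texture and nuclear-shape morphometry.

Tumor hypoxia — oxygen shortage inside solid tumors — changes both gene
expression and tissue morphology, and matters clinically because hypoxic
regions resist radiotherapy. Quantifying it normally requires RNA
sequencing and a hypoxia gene signature, an extra assay on top of routine
pathology. `hypomil` implements the alternative: learn the morphologic
correlates of hypoxia directly from routine H&E slide images, using only
*weak*, sample-level labels derived from a hypoxia metagene score, then
interrogate what the model found with classical morphometry. The package
is aimed at computational-pathology researchers who want a tested,
CPU-friendly reference implementation of this analysis, exercised
end-to-end on synthetic histology-like data with planted, recoverable
signal.

## The analysis

**Weak labels.** For a cohort expression matrix and a hypoxia signature
gene set (e.g. the 52-gene Buffa signature), each sample's score is the
median-split metagene sum

    score(k) = Σ_g [ +1 if x_gk > median_g else −1 ],   g ∈ signature,

so score ∈ [−G, +G] for G signature genes. Samples with score > 0 are
labelled hypoxic; hypoxic samples split further into a low (0 < score ≤ 20)
and a high (score > 20) stratum for per-stratum evaluation.

**Multiple-instance learning.** Each slide is tiled into 256 × 256 px
tiles; a tile's tissue fraction is the share of pixels below the tile's own
Otsu threshold in grayscale, and tiles with ≤ 50 % tissue are discarded. A
bag of N tiles per sample (N = 20 at training, resampled every epoch; all
tiles at inference) passes through a convolutional encoder; global average
pooling plus a linear projection yields one 512-feature vector F_kⁱ per
tile, and the bag is classified as

    L_k = softmax( relu( Pool(F_k¹, …, F_kᴺ) ) · W₁ + b₁ ),

where Pool is either the element-wise maximum or gated attention pooling
(a learned convex combination with weights softmax(wᵀ(tanh(V F) ⊙ σ(U F)))).
Training is plain SGD with cross-entropy. Two encoders are provided: a
compact `small_cnn` that trains in minutes on one CPU, and a `vgg19_like`
stack for full-scale use. Gradient-weighted class-activation maps localize
the image regions driving each call.

**Morphometry.** High-confidence tiles (scored as bags of one instance) are
compared between predicted classes using gray-level co-occurrence matrix
texture features at distance 1, averaged over the 0°/45°/90°/135° angles:

    Homogeneity = Σᵢⱼ P(i,j)/(1+(i−j)²),  Energy = Σᵢⱼ P(i,j)²,
    Correlation = Σᵢⱼ (i−μᵢ)(j−μⱼ)P(i,j)/(σᵢσⱼ).

Per-cell annotation masks yield binary shape descriptors:

    Eccentricity = √(1 − b²/a²),  Circularity = 4π·Area/Perimeter²,
    Extent = A_object/A_BBox,

plus area, perimeter, solidity and equivalent diameter. Group differences
use a two-sided Mann–Whitney U test with the conventional star ladder.

## Worked example

The bundled demo generates a 32-sample synthetic cohort (16 per class) in
which hypoxic samples get coarser tissue texture, elongated nuclei
(axis ratio 2) and an up-shifted signature-gene block, then runs the whole
pipeline — tiling, Otsu filtering, weak-label scoring, two stratified
train/test splits, MIL training, per-stratum evaluation, and both
morphometric comparisons (about 1½ minutes on one CPU):

```sh
hypomil run --config examples/demo.yaml --out demo_out
```

`demo_out/metrics.json` then reports

    AUROC (all):  mean 1.0, sd 0.0  over 2 splits
    AUROC (high): mean 1.0, sd 0.0
    AUROC (low):  undefined — no sample lands in 0 < score ≤ 20 because the
                  planted 5-SD signature shift makes scores extreme

and `texture_comparisons.csv` / `shape_comparisons.csv` recover the planted
morphology from the model's own calls:

    homogeneity    hypoxic 0.363  normoxic 0.310   p = 3e-06   ****
    dissimilarity  hypoxic 3.93   normoxic 5.98    p = 3e-16   ****
    eccentricity   (epithelial)  hypoxic 0.866  normoxic 0.000  ****
    circularity    (epithelial)  hypoxic 0.843  normoxic 1.010  ****

The called-hypoxic tiles are smoother at pixel scale (higher homogeneity,
lower dissimilarity — the planted coarse-granularity texture), and the
called-hypoxic epithelial nuclei measure exactly the planted axis-ratio-2
eccentricity √(1 − 1/4) ≈ 0.866 while the round normoxic nuclei measure 0.
Everything is seeded: re-running the same config reproduces every output
file byte-for-byte (hashes in `demo_out/manifest.json`).

The same stages are available as library calls (`generate_slides`,
`tile_slide`/`filter_tiles`, `BuffaScorer`, `HypoxiaMILClassifier`,
`tile_texture_features`, `shape_descriptors`, `compare_groups`) — the
estimator follows scikit-learn conventions (`fit`, `predict_proba`,
`get_params`) and composes with sklearn model selection.

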