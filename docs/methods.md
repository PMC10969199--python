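# Methods

## The construction problem

`wcesim` builds a capsule-endoscopy-styled classification dataset out of
wired-endoscopy images in six stages: source acquisition → color transfer
→ similarity gating → balancing augmentation → optional sharpen/detail
preprocessing → stratified splitting. This note records the model behind
each stage, the defaults and why, the numerical conventions, and what the
synthetic data does and does not establish.

## Color model and transfer

The transfer operates in the l·α·β opponent space: RGB is mapped by the
standard linear RGB→LMS matrix, followed by an elementwise base-10
logarithm and the fixed decorrelation map with diagonal scalings 1/√3,
1/√6, 1/√2. The log argument is the intensity normalised to [0, 1] and
floored at 1/255, so pure black is representable and the forward map is
exactly invertible for intensities ≥ 1 (round trips deviate by at most one
intensity level, from the final rounding). These matrix constants come
from the original publication of the algorithm; the forward/inverse pair
is computed from a single matrix definition so the two directions cannot
drift apart.

Transfer itself is per-channel affine moment matching:
`out_k = (σ_t/σ_s)(S_k − mean S_k) + mean T_k`. Its defining property —
the result's channel means/SDs equal the target's — is asserted on the
pre-clipping lab representation; gamut clipping happens only at the final
RGB conversion. A source channel whose SD is below 1e-8 is treated as
constant (σ = 0) and mapped to the constant target mean: a computed SD of
order 1e-16 on a constant image is float round-off, not signal, and the
affine branch would amplify it catastrophically. Statistics use the
*population* SD (ddof = 0); at thousands of pixels per image the
sample/population distinction is immaterial, but one convention must be
fixed for bit-reproducibility.

Multiple reference images per style are pooled into one target statistic:
pixel-count-weighted mean of means, root-mean-square of SDs. Pooling is
the default because it is deterministic and treats the reference set as
one target distribution; a per-reference round-robin mode exists for
comparison. An `space="rgb"` mode applies the same match directly on R,
G, B channels; lab is the default because the decorrelated channels can
be matched independently without hue artefacts.

An optional near-black mask (exclude pixels whose max channel < 10) keeps
the circular black border of endoscopy frames out of the reference
statistics; it is off by default and enabled per config.

## Embeddings and the gate

Similarity is measured between embeddings, not pixels. The built-in
`colorgrid` embedder resizes to 32×32 (plain bilinear, no anti-aliasing —
chosen for exact reproducibility), converts to lab, and takes mean and SD
per channel over a 4×4 spatial grid: 96 features capturing the color
distribution and its coarse layout. A `cnn` slot accepts any
user-supplied feature extractor (the classical choice is an
ImageNet-pretrained VGG16's penultimate layer); the package never
downloads weights on its own.

Every embedding is L2-normalised. This is the load-bearing convention:
unit-norm vectors bound all pairwise Euclidean distances to [0, 2] and
give the identity d² = 2(1 − cosine similarity), so a fixed acceptance
cutoff is meaningful regardless of the embedding method's native scale.

The gate accepts a transferred image when its distance to the style's
references is ≤ threshold + tolerance, default 1.0 + 0.2 = 1.2. Only the
upper side of the band is enforced — a distance near 0 is maximal
similarity and always passes. "Distance to the references" is the minimum
over the style's reference embeddings (the conservative reading when
several references stand in for one target; a mean-distance mode is
available). Rejected records are never deleted: they stay in the
manifest with their distance, flagged unaccepted, so the filtering is
auditable.

## Augmentation and balancing

The named transforms — left-right inversion, top-down inversion, and a
20° tilt — generate the variant budget as the product set
{identity, hflip, vflip, hflip∘vflip} × {none, +20°, −20°}: 12 distinct
variants per source including the original. The composed set is needed
because three stand-alone transforms cannot expand a 207-image class to
1280 (a factor of ≈ 6.2). Rotation keeps the original canvas with black
corner fill, matching the dark borders of endoscopy frames, and uses
bilinear resampling.

`balance_class` reaches the target count exactly: all originals first,
then variants in rounds (every source receives its k-th variant before
any source receives its (k+1)-th), the final partial round drawn by
seeded sampling without replacement. Consequently variants-per-source
differ by at most one, no (source, chain) pair repeats, and the result is
deterministic under a fixed seed. Balancing produces a *plan* of
(record, chain) pairs; pixels are only materialised by the build stage,
so counting and splitting are cheap.

The gate runs *before* augmentation: variants inherit acceptance from
their source, being color-identical up to resampling, and gating cost
stays per-source rather than per-variant.

## Filters

"Sharpen" and "detail" are defined by explicit kernel constants —
[[−2,−2,−2],[−2,32,−2],[−2,−2,−2]]/16 and [[0,−1,0],[−1,10,−1],[0,−1,0]]/6
— with edge-replicate padding, clipping to [0, 255] and rounding. Naming
an imaging library's filters would tie behaviour to that library's
internals; fixing the de-facto kernels of the widely used filters of
these names makes the operation bit-reproducible anywhere. Both kernels
sum to their scale, so constant images are fixed points. The combined
filter is sharpen followed by detail, in that order; the composition is
not commutative and the order is part of the contract. When a filter is
requested in a build, the filtered dataset is written as its own tree and
the filter name is appended to each record's transform chain, so original
and filtered datasets coexist as siblings.

## Split and metrics

The stratified splitter floor-allocates each class across
train/val/test from the ratio (default 6:2:2) and hands remainders out in
ratio order, so 1280 per class gives exactly 768/256/256 and the
study-scale totals 3840/1280/1280. Record-level splitting is the default;
`group_by_source` keeps all variants of one source in one partition
(sizes then only approximate the ratio). Record-level splitting of
augmented data lets variants of one source land in different partitions —
a leakage the grouped mode exists to avoid; the default reproduces the
conventional protocol and the limitation is documented here deliberately.

Metrics are the standard confusion-matrix family. The task is 5-class, so
precision/recall/F1 are computed one-vs-rest per class and macro-averaged
without weighting; any 0/0 rate is defined as 0 (affects classes never
predicted). Accuracy is trace/total.

## Synthetic data: what it emulates, what it does not

The generator fabricates endoscopy-*like* frames: an oriented sinusoidal
"fold" texture per class (orientations 0°/36°/72°/108°/144°, per-class
frequency and amplitude), drawn directly in lab space around a style's
target channel statistics, plus Gaussian lab noise (SD 0.05), converted
to RGB and masked with a circular black vignette (radius 0.95 of the
half-frame). Styles: "wired" is bright and pink (lab mean l −0.50);
capsule styles "L", "R", "G" are darker and warmer (l −0.85 to −1.00,
distinct α/β offsets) so the three capsule variants are statistically
separable. The style means were chosen once from representative
bright-pink and dark-orange endoscopy colors; the wired/capsule
luminance gap (≥ 0.2 in l) is what the style-transfer stage must bridge.
The default class distribution is 493/901/533/392/207 (total 2526),
mirroring the five-landmark source data the pipeline targets.

Two statistical properties make the synthetic data a meaningful test
bed: transfer moves wired frames measurably closer to capsule references
in embedding space (style recovery, ≥ 95% of frames across seeds), and a
nearest-centroid classifier on colorgrid embeddings beats 5-class chance
comfortably (class signal). What the synthetic data does *not* establish:
anatomical realism, realistic intra-class variability, capsule-specific
artefacts (specular highlights, bubbles, motion blur), or any claim about
classification accuracy on real endoscopy images. Passing tests show the
*pipeline machinery* is correct and deterministic, not that a classifier
trained on its output will transfer to the clinic.

With the weight-free colorgrid embedder the observed gate distances on
synthetic data sit far below the 1.2 cutoff (order 0.01–0.03 after
transfer); the acceptance band becomes binding only with
higher-dimensional texture-sensitive embedders such as the CNN slot.

## Problem sizes and determinism

Unit tests run at 16–64 px frames and small class counts; the
demonstration script (`scripts/acceptance.py`) runs the full
2526-source, three-style, 1280-per-class construction at 64 px — channel
statistics and all counting logic are resolution-invariant, so the small
frame size only speeds up pixel work. Every stochastic step (partial
augmentation round, split shuffling, synthesis noise) derives its
generator from the run seed plus fixed stage/style/class indices, so a
build is byte-reproducible end to end: same config + seed ⇒ identical
images, manifests and reports.

## Known limitations

- The colorgrid embedder is color-dominated by design; it will not
  penalise geometric corruption the way a CNN feature space would.
- Record-level 6:2:2 splitting of augmented data leaks sources across
  partitions (see above); use `group_split` when that matters.
- The gate band (1.0 + 0.2) is a configurable constant, not an estimated
  quantity; no outlier-simulation procedure for re-deriving it is
  included.
- JPEG sources are decoded losslessly into memory, but all
  artifact-generated images are written as PNG; JPEG re-encoding losses
  are out of scope.
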