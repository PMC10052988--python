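# Methods

This note records the models implemented in `tileqc`, the defaults and why
they were chosen, what the synthetic fixtures do and do not demonstrate,
and the numerical and design decisions a maintainer should know about.

## Optical-density model and stain separation

Light transmitted through a stained section follows Beer–Lambert
absorption, so stains combine additively in optical density rather than in
RGB.  We define

    od_c = −log10((p_c + 1) / (i0 + 1)),   p_c ∈ {0, …, 255},  i0 = 255,

per channel.  The `+1` offset makes the transform total (no log 0) and,
with the matching `i0 + 1` denominator, gives `od = 0` exactly at the
white level, keeps OD nonnegative over the whole 8-bit range, and makes
the RGB↔OD round trip bit-exact for all 256 channel values (tested
exhaustively).  The darkest pixel maps to `log10 256 ≈ 2.408`.

A two-stain model is used throughout: pixel OD ≈ `S·c` with `S ∈ ℝ³ˣ²`
(unit-norm hematoxylin and eosin columns, all components ≥ 0) and `c ≥ 0`.
There is no third/residual channel; the pipeline addresses H&E sections
only.

### Stain-vector estimation (Macenko)

1. Discard transparent pixels: keep pixels with ‖od‖₂ ≥ β (β = 0.15).
   The magnitude criterion matters: a per-channel threshold would discard
   near-pure eosin pixels (eosin's red-channel OD component is ≈ 0.07)
   and bias the eosin estimate by several degrees.
2. Project the retained OD cloud onto its two leading principal
   directions (eigendecomposition of the covariance; basis sign fixed so
   median projection is positive).
3. Take the α and 100 − α percentile angles of the projected cloud
   (α = 1) and map them back to unit 3-vectors, clipping tiny negative
   components.
4. Order columns: hematoxylin is the vector with the larger red-channel
   OD component.  Blue-purple nuclei absorb red strongly while pink
   eosin transmits it, so the red component separates the stains robustly;
   for the conventional published vectors the red components are 0.65 vs
   0.07.
5. Degeneracy: fewer than 100 tissue pixels, a rank-1 OD cloud, or an
   estimated pair closer than `min_angle_deg` (20°) raises a
   degenerate-input error.  The angular floor matters in practice: on
   tiles that are blank-ish, blurred, or nearly single-stain the two
   percentile extremes collapse toward each other (8–13° observed on
   synthetic artifact tiles, vs ≥ 22° on well-populated ones) and the
   resulting unmixing is ill-conditioned.

On forward-synthesized two-stain tiles the estimator recovers both
columns within 0.2° (2° is the tested bound, over 20 seeds).

### Concentrations, normalization, H channel

Concentrations are the per-pixel least-squares solution of `od ≈ S·c`
(pseudo-inverse, negatives clipped to zero).  Normalization to a
reference rescales each stain's concentration so its 99th percentile
matches the reference (`max_conc`, default (1.9, 1.0)) and reconstructs
through the reference stain matrix (default: the conventional published
H&E vectors H ∝ (0.65, 0.70, 0.29), E ∝ (0.07, 0.99, 0.11), unit
normalized).  H-channel extraction zeroes the eosin concentration before
reconstruction, sending cytoplasm and background to white while nuclei
stay dark.

Known limitation: concentration rescaling amplifies whatever small
concentrations the background carries.  Truly blank (zero-concentration)
pixels are invariant and stay white to within rounding (±3 tested), but a
faintly tinted background on a slide much more lightly stained than the
reference can visibly darken.  This is inherent to percentile-matching
intensity normalization, not an implementation artifact.

## Cluster-mask quality filter

Per tile: map pixels to the configured feature space → k-means on the
3-channel colors (no spatial features) → select the nuclear cluster →
whiten everything else → score = retained-pixel fraction → threshold.

- **Feature space** defaults to `h_channel` (eosin-subtracted
  reconstruction), where nuclei separate best; `original_rgb` and
  `normalized_rgb` are selectable.
- **The h-channel transform uses the configured reference stain matrix,
  not a per-tile estimate.**  Per-tile estimation inside the filter is
  circular: the degenerate tiles the filter exists to catch are exactly
  the tiles on which estimation fails, and on good tiles a perfect
  per-tile subtraction merges the eosin residue with the background so
  k-means splits the nuclei cluster instead of the light pixels.  Fixed
  vectors also keep scores comparable across tiles.
- **K-means**: scikit-learn's k-means++ / Lloyd iterations, one restart,
  fixed seed (`n_init` configurable; on tiny synthetic instances with
  three distinct colors a single restart misses the global optimum a few
  percent of the time, and the exhaustive-oracle equivalence tests use
  restarts accordingly).  `k = 3` default, `k = 4` supported; 2 ≤ k ≤ 10.
- **Nuclear-cluster selection**: centroid colors are pushed through the
  concentration solve; the cluster with maximal hematoxylin concentration
  wins (ties: darker centroid, then lowest index).  In the filter the
  winner must additionally reach `nuclear_conc_min` = 0.25 OD — about a
  third of a typical nucleus concentration.  Without this floor the
  argmax always selects *something*, so an eosin-only or blurred tile
  with no sharp nuclei would have its whole cytoplasm cluster retained
  and score ≈ 0.3 "good".  A tile with no qualifying cluster scores 0.
- **Threshold** τ = 0.05 (configurable), matching the generator's
  labeling threshold so that synthetic-slide evaluations are
  self-consistent; the boundary is inclusive (score = τ → good).
- Blank tiles (fewer than 100 pixels above β) score 0 and are routed to
  the poor set with a recorded reason rather than aborting the run.

On generated slides the filter recovers a 30% poor mixture to within a
couple of tiles and its scores track true nuclear coverage with Spearman
ρ typically ≥ 0.8 at both k = 3 and k = 4 (≥ 0.96 at k = 3).

## Synthetic tile generator

Each tile is a pure function of its spec (all randomness from the seed;
byte-identical reruns).  Rendering: near-white background (245, 243, 245)
with ±3 noise; soft eosin-pink elliptical blobs (230, 140, 170) covering
roughly 40%; purple elliptical nuclei (90, 60, 150) with per-nucleus
color jitter added until the nucleus raster reaches the requested
coverage (trailing nuclei shrink to the remaining budget so sparse tiles
cannot overshoot).  The true nuclear fraction is counted from the
generator's own nucleus raster.  Artifacts are applied last: `blank`
suppresses tissue, `blur` Gaussian-smooths with σ = 3% of the tile
extent, `fold` overlays a dark saturated band ≈ 2.5% of the tile tall.

A tile is labeled **good** iff its true nuclear fraction ≥ 0.05.  Slides
draw exactly `round(n × fraction_poor)` poor tiles; poor tiles are
sampled uniformly from {blank, blurred (density ≤ 0.02), folded
(density ≤ 0.01), low-density (0.005–0.03)}, good tiles from density
0.10–0.40 with no artifact.  The density bands are deliberately separated
from the 0.05 threshold by at least the rendering granularity so labels
are unambiguous; default tile extent is 128×128.

**What the fixtures do not show.**  The generator produces flat-shaded
ellipses, not chromatin texture; its artifact classes are idealized; its
color palette is fixed and cleanly separable in OD space.  Passing tests
demonstrate that the pipeline's mechanics (stain algebra, clustering,
masking, scoring, training protocol) are correct and self-consistent —
they say nothing about accuracy on scanner imagery, real staining
variability, or doctor-rated tile quality, and the published ~80%
accuracy of a quality CNN on expert-rated slide tiles is explicitly not
reproduced here (that data is unavailable).

## Quality CNN

Default network: conv–ReLU–maxpool blocks with 3×3 kernels and filter
widths doubling from 16, a 64-unit dense layer, dropout 0.25 (after
flatten) and 0.5 (after dense), sigmoid output, binary cross-entropy.
Input 256×256 with a 128 variant; tests and desk-scale runs use 64×64
with two blocks.  Optimizer: Adam, learning rate 0.001 (bias-corrected
moments, standard β₁ = 0.9, β₂ = 0.999).  Protocol: stratified 40% test
split; a stratified 10% validation slice of the training set provides
per-epoch curves; augmentation (horizontal/vertical flips, ±15°
rotation, ±5% shifts) is applied on the fly to the training stream only.
Desk-scale runs train 10 epochs with batch size 8 — with ~100 training
tiles that is enough Adam steps to separate the synthetic classes, and a
run finishes in well under a minute on one CPU.

The backend is a numpy implementation written for this package (im2col
convolution, 2×2 max-pooling, inverted dropout, explicit backward passes)
and is verified end to end by finite-difference gradient checks.  Splits,
batch order, augmentation draws and weight initialization all derive
from the config seed; bitwise weight reproducibility across BLAS builds
is best-effort, while sample ordering is strictly deterministic.

Overfitting detection: the first epoch at which validation loss has not
improved for `patience` epochs (default 5) while training loss is still
below its value at the last validation improvement; `None` if the curves
never diverge.  On curves that flatten at epoch 20 with patience 5 the
detector reports epoch 25.

## Architecture accounting

Parameter totals are closed-form sums: `k_h·k_w·c_in·c_out + c_out` per
biased conv layer, `n_in·n_out + n_out` per biased fc layer, zero for
pooling/flatten; inception blocks sum their six branch convolutions.
Every shipped spec passes shape propagation from its input extent before
counting.  AlexNet is modeled as a single ungrouped stack (five conv
layers with kernels 11, 5, 3, 3, 3 and filters 96, 256, 384, 384, 256;
fc 4096, 4096, 1000 from a 6×6×256 map), which yields exactly
62,378,344 parameters; the two-GPU grouped variant would not.  VGG16's
thirteen 3×3 convolutions plus three fc layers yield 138,357,544.
GoogLeNet is the canonical inception-v1 table (22 weight-bearing layers
counting each inception block as two); its total (≈ 7.0M) and LeNet-5's
(61,706) are reported as informational — figures sometimes quoted for
"GoogLeNet" (23M) correspond to later Inception revisions, and
8,062,504-parameter "LeNet with shortcut connections" matches no
canonical LeNet, so neither is asserted.  No batch normalization
anywhere; biases included throughout.

## Determinism and problem sizes

Every stochastic stage (generation, clustering, splitting, training)
takes an explicit seed, and multi-stage runs derive stage seeds from one
global seed.  Shipped evaluations use desk-scale sizes — 200-tile slides,
128×128 tiles for filtering, 64×64 tiles and 10 epochs for training —
chosen so the full pipeline (and its tests) run in minutes on a single
CPU while leaving every algorithmic path exercised.
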