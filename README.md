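# tileqc

Quality control for hematoxylin–eosin (H&E) histology tiles.

Digitized breast-carcinoma slides are cut into thousands of fixed-size
sub-images before a classifier ever sees them, and a large share of those
tiles — blank glass, out-of-focus fields, tissue folds, regions with almost
no tumor cells — carry no usable signal.  `tileqc` implements the
preprocessing stack that separates informative tiles from uninformative
ones:

- **Stain math in optical-density space.**  Under Beer–Lambert absorption,
  pixel OD is a nonnegative linear mix of two unit stain vectors,
  `od ≈ S·c` with `S ∈ ℝ³ˣ²` (hematoxylin, eosin columns).  The package
  estimates `S` per image with the Macenko procedure (extreme-percentile
  angles of the OD cloud on its leading principal plane), normalizes
  staining intensity to a reference by rescaling the 99th-percentile
  concentrations, and extracts the eosin-subtracted **H channel** — the
  image reconstructed from hematoxylin concentration alone, which isolates
  nuclei.
- **K-means cluster-mask tile scoring.**  Pixels of each tile (by default
  in H-channel colors) are clustered with seeded k-means (`k = 3` default,
  `k = 4` supported); the cluster whose centroid carries the most
  hematoxylin is kept and everything else is whitened.  The
  **non-white-pixel proportion** of the resulting mask is the tile's
  quality score; thresholding it (τ = 0.05) yields a binary good/poor
  verdict.
- **A binary quality CNN** trained with a fixed protocol — stratified 40%
  test split, flip/rotation/shift augmentation, dropout, Adam at learning
  rate 0.001 — plus learning-curve–based overfitting detection.  The
  training backend is a compact, fully tested numpy implementation
  (im2col convolution, max-pooling, dense layers, Adam).
- **Verified neural primitives**: the threshold perceptron with its
  delta-rule update `wᵢ ← wᵢ + α(d − y)xᵢ`, and 2-D cross-correlation
  `C(i,j) = Σₓ Σᵧ w(x,y) f(x+i, y+j)`, each checked against brute-force
  oracles.
- **An architecture zoo** with closed-form parameter accounting: AlexNet
  (62,378,344 parameters), VGG16 (138,357,544), GoogLeNet (inception-v1)
  and LeNet-5, all validated by shape propagation.
- **A synthetic H&E tile generator** — purple elliptical nuclei over pink
  eosin blobs on a near-white background, plus blank / blurred / folded
  artifact tiles — with exact per-tile ground truth, so the entire
  pipeline is testable without any slide data.

Everything is exposed both as scikit-learn-style estimators
(`StainNormalizer`, `ClusterQualityFilter`, `QualityCNN`,
`PerceptronClassifier`) and as a `tileqc` command-line tool.

## Worked example

Generate a labeled synthetic slide of 50 tiles with a 30% poor-quality
mixture, then run the cluster-mask filter over it:

```sh
$ tileqc simulate --n-tiles 50 --fraction-poor 0.3 --tile-size 128 --seed 7 --out demo/slide
wrote 50 tiles and demo/slide/manifest.tsv

$ tileqc qc-filter --k 3 --seed 7 --out demo/filtered demo/slide
good: 35  poor: 15 (30.0% flagged poor)
```

The filter recovered the generated mixture exactly: 15 of 50 tiles
(blank, blurred, folded, or nearly nucleus-free) score below τ = 0.05 and
land in `demo/filtered/poor/`.  Per-tile scores are written as a
tab-delimited table:

```
tile_id     non_white_fraction  label  k  feature_space  reason
tile_0000   0.020263671875      poor   3  h_channel
tile_0001   0.28167724609375    good   3  h_channel
```

`non_white_fraction` is the share of pixels retained by the nuclear
cluster mask — for good tiles it tracks the true nuclear coverage of the
generated tile (Spearman ρ ≥ 0.8 across a slide).

Closed-form parameter accounting needs no training framework:

```sh
$ tileqc count-params alexnet
conv1        55x55x96        34,944
pool1        27x27x96             0
conv2       27x27x256       614,656
...
fc8              1000     4,097,000
total                    62,378,344
```

From Python, the same stages compose as estimators:

```python
from tileqc import ClusterQualityFilter, generate_slide, SlideSpec

tiles = generate_slide(SlideSpec(n_tiles=50, fraction_poor=0.3, seed=7))
labels = ClusterQualityFilter(k=3, seed=7).fit().predict(tiles)
print((labels == "poor").mean())   # 0.3
```

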