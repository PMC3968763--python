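# Methods

## PHOG image statistics

Images are 8-bit RGB rasters. Before analysis each image is resampled
bicubically to a fixed pixel budget (default 100,000 pixels, aspect ratio
preserved); a fixed budget makes the per-pixel statistics comparable across
images of different native resolutions and suppresses scanning/halftone
artifacts in digitized material. The aspect ratio is always taken from the
original dimensions.

The gradient field is computed in CIE Lab (sRGB → D65 Lab; the conversion
dialect of legacy image editors is not reproducible, so the standard CIE
pipeline is used). Each channel is differentiated with centered differences
([−1, 0, 1]/2 per axis) and edge replication at borders — the minimal
operator consistent with standard HOG practice; the operator is isolated in
one helper and swappable. Per pixel, the channel with the largest gradient
magnitude supplies both magnitude and orientation. Zero-magnitude pixels
carry the sentinel orientation 0° and contribute no histogram mass.

Orientation histograms have 16 equal bins covering 360°, accumulate
gradient magnitudes, and are L1-normalized (the intersection kernel is then
bounded by 1). A region with zero gradient mass is flagged degenerate
rather than normalized. The pyramid tiles the image with 2^ℓ × 2^ℓ
rectangle grids for levels ℓ = 0…3; rectangle bounds come from integer
division, with remainder pixels absorbed by the last row/column of
rectangles.

Derived statistics:

* **Self-similarity** = median over the 64 level-3 subregions of
  HIK(level-3 histogram, level-0 histogram). The median is robust to a few
  degenerate blocks (which contribute intersection 0); the mean is
  available as an option. A zero-gradient image has undefined
  self-similarity and is flagged.
* **Complexity** = mean gradient magnitude. The total gradient strength
  divided by pixel count; with the fixed pixel budget, sum and mean differ
  only by a constant factor, and the mean is explicitly size-invariant.
* **Anisotropy** = population SD of the normalized bin values pooled over
  all non-degenerate level-3 histograms (16 × 64 values). 0 for
  orientation-uniform images; identical one-hot histograms attain the
  pooled maximum √15/16 ≈ 0.242. A per-histogram-SD-then-average variant is
  available; degenerate blocks are excluded rather than contributing zero
  bins, and an all-degenerate level is flagged missing.
* **Birkhoff-like measure** = self-similarity / complexity (undefined when
  complexity is 0 or self-similarity is flagged).

Color statistics are plain per-channel means in HSV ([0, 1]), RGB
([0, 255]) and Lab (L in [0, 100], signed a/b). Hue is averaged
arithmetically by default to match how such tables are usually reported,
with a circular mean as an opt-in; the circularity of hue is addressed
separately by the six-sector analysis (60° sectors centered on red,
yellow, green, cyan, blue, magenta). Pixels with saturation < 0.05 have
numerically unstable hue; they are assigned by their raw hue but counted in
a separate achromatic tally.

## Behavioral layer

Ratings are integers 1–4 (1 = most beautiful, the German school-grade
convention); the baseline matrix must be complete. Rater clustering is
k-means in image-rating space (Euclidean distance, seeded k-means++ with
100 restarts, best within-cluster sum of squares kept). Diagnostics per
k = 2…10: WSS; a spherical-Gaussian BIC with shared variance
σ² = WSS/(d(n−k)), BIC = n·d·ln σ² + k(d+1)·ln n; and Dunn's index as
minimum inter-centroid distance over maximum intra-cluster diameter.
A minimum cluster size of 4 participants marks experimental feasibility.

Adaptor selection ranks images by cluster-mean rating ascending, ties
broken by image id: the first/last 15 are the most-/least-beautiful adaptor
sets, and the evaluation set is the 60 images centered in the ranking of
the remaining images ("average-rated"); with strictly monotone means over
150 images this is exactly ranks 1–15, 46–105 and 136–150.

## Perceptual contrast

contrast(image) = mean rating after beautiful adaptors − mean rating after
least-beautiful adaptors, pooled per cluster over the participants who
rated the image in both conditions; positive contrast = rated less
beautiful after beautiful adaptors. The global test is a paired t-test
across the pooled unique evaluation images, averaging within image across
the clusters that evaluated it (the exact pooling used in earlier reports
of this design is not documented; this rule is the package's choice and
both per-cluster and pooled views are emitted). The per-cluster summary
flags clusters whose mean contrast opposes the majority sign — the
anomalous-cluster phenomenon. Zero variance of the paired differences is
flagged degenerate instead of producing an unstable t.

## Association layers

Spearman correlations are tie-corrected (mean ranks); p-values use the
t-approximation, appropriate for n = 150 images. Raw p-values are reported
(mirroring common practice for such tables) alongside Holm-adjusted
values. A positive ρ means images with more of the property were rated
less beautiful.

The multivariate regressions z-score the response and every predictor, so
OLS coefficients are standardized β; with a single predictor the β equals
the Pearson correlation. Constant predictors are dropped with a warning
(their standardized β is undefined); a design-matrix condition number
above 1e6 raises a collinearity warning but coefficients are still
reported. An optional quadratic probe (rating ~ complexity + complexity²)
covers the inverted-U hypothesis for complexity.

The mixed model treats (image, cluster) pairs as observations: dependent =
cluster-mean rating, fixed = cluster membership, covariates = z-scored
image properties, plus cluster × property interactions; the random
structure is an intercept per image — the only grouping factor left once
cluster is fixed, stated here as an assumption. Interactions are tested
with Wald chi-square statistics reported on the F = χ²/df scale (the mixed
model has no exact finite-sample F); per-cluster regression coefficients
are the base slope plus the cluster's interaction term, with Wald
p-values. Singular or non-converged fits are reported as such, never
silently replaced.

## Synthetic data

The generators emulate the study conditions so that every stage has known
ground truth:

* `periodic_tiling` — a toroidally periodic smoothed-noise tile repeated
  8 × 8; every level-3 block sees identical content → self-similarity ≈ 1.
* `block_mosaic` — 8 × 8 oriented ramp patches assembled as a globally
  continuous separable field I(x, y) = A(x) + B(y) with half-integer
  per-block slopes. Continuity avoids spurious seam gradients and
  half-integer slopes make centered differences exact on the 8-bit grid, so
  each level-3 histogram is one-hot: low self-similarity and anisotropy at
  the √15/16 maximum. (Sinusoidal gratings cannot produce one-hot
  histograms over 360°: their gradient mass necessarily splits between two
  opposite bins.) The slope sets are chosen so no block orientation falls
  within ~4° of a bin boundary.
* `spectral_noise` — random-phase noise with amplitude spectrum f^(−α);
  α monotonically lowers measured complexity.
* `color_field` / palette tints — spread the collection over hue,
  saturation, value and lightness.

The default 150-image collection cycles these kinds with graded parameters
and varied sizes (so the aspect ratio is non-constant) and spans ≥ 0.4 of
the unit interval in measured self-similarity.

The rating model is linear-in-features with Gaussian noise — an assumption
of this package, not an empirical claim: participant p in latent cluster g
rates image i as round(clip(a_g + w_g·z_i + ε, 1, 4)), ε ~ N(0, σ²), with
z the standardized features. The default population has 50 raters in 7
clusters of sizes 10/9/7/7/7/6/4, taste weights of magnitude 0.2–0.4 with
mixed signs on self-similarity across clusters, and rating noise σ = 0.8.
σ = 0.8 was chosen because, at the reported design scale (42 raters, 132
evaluation images, shift 0.16), it puts the paired t statistic near 10 and
image-level SDs near 0.2 — the scale reported for this design — while
keeping ratings spread over the whole 1–4 range. Intercepts are calibrated
so the rounded, clipped grand mean is ≈ 2.88 (the reference mean rating);
rounding and clipping pull the raw mean down slightly, hence intercepts
average ≈ 2.93.

Adaptation is modeled as a symmetric condition shift ±δ_i/2 with
δ_i = δ0 + δ1·z_ss(i) (defaults δ0 = 0.16, δ1 = 0.04, linking contrast
positively to self-similarity); the mechanism (neural adaptation, criterion
shift, or comparison) is deliberately left open, matching the ambiguity of
the behavioral literature. One default cluster (index 4) has the shift sign
inverted, emulating the anomalous cluster observed in this design; the
condition order is counterbalanced and recorded but has no modeled effect.
Participants' utilities always follow their latent generating cluster,
while the experiment's (possibly imperfect) k-means assignment decides
which evaluation set they rate — so imperfect clustering attenuates the
pooled contrast exactly as it would in a real study.

`separated_population(separation_sigma=s)` builds populations whose
clusters each load weight s·σ/√2 on a distinct feature, making the
per-image SD of the expected-rating difference between any two clusters
equal to s noise SDs; at s = 3 the k-means recovery of the partition is
essentially perfect (ARI ≈ 1).

### What the synthetic data does and does not show

The generators produce stationary textures and clean cluster structure;
real artworks have composition, semantics, correlated feature
distributions and much lower predictability (the default generator's
beauty-regression R² is far above what real rating data yields). Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline* — not that any empirical effect exists in real paintings.

## Numerical choices and problem sizes

* Histograms normalize with L1; degenerate (zero-mass) regions are flagged,
  never divided.
* Ties in adaptor selection and image ordering break by image id; all
  stochastic steps take explicit seeds; reruns of the pipeline are
  bit-identical per stage.
* Test and acceptance simulations use 40–150 images, 24–50 raters, and
  400–1000 replicates for calibration checks — sizes chosen to estimate the
  relevant rates (e.g. a type-I error of 0.05 ± 0.014 at 1000 replicates)
  while keeping a full run in the low minutes.
* Brute-force oracles (double-loop HOG, rank-based Spearman, paired t,
  difference-regression F) live in the test suite and share no code with
  the implementation.

## Known limitations

* The Lab conversion dialect differs from legacy commercial editors;
  absolute complexity values are therefore not comparable across toolchains
  (self-similarity and anisotropy are normalized and robust to this).
* The mixed model reports Wald/χ² interaction tests, not finite-sample F
  tests; for small image counts p-values are approximate.
* Oblique (non-axis-aligned) ramp gratings on an 8-bit grid show small
  orientation quantization jitter; the mosaic generator avoids it by
  construction, but user-supplied low-contrast oblique gradients may
  scatter mass into neighboring bins.
* The plain hue mean is reported for comparability with legacy tables even
  though hue is circular; use the circular option or the sector analysis
  for circular-safe statements.
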