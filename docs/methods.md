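# Methods

`histotex` quantifies tissue damage and protection in histology studies by
combining statistical texture analysis of micrographs with unsupervised
neural-network clustering of per-sample descriptors. This note records the
models, the conventions behind every numerical choice, what the synthetic
generators do and do not emulate, and the known limitations.

## Pipeline overview

1. **Preprocess** — read an RGB micrograph, collapse to luminance, quantize
   gray levels.
2. **Texture features** — 65 descriptors per image from the co-occurrence,
   run-length and gradient families.
3. **Feature selection** — rank descriptors by Fisher coefficient, keep the
   top k (texture route only; an eight-indicator assay table is used whole).
4. **Clustering** — two-cluster winner-take-all competitive learning on
   standardized features.
5. **Characterization** — group-by-cluster percentage tables canonicalized
   by two reference groups, and weighted-average descriptor profiles.

## Preprocessing

Luminance uses the fixed ITU-R BT.601 weights 0.299 R + 0.587 G + 0.114 B
with half-up rounding, so conversion is bit-reproducible. Quantization
(default 64 levels, `minmax`) maps the observed intensity range onto equal
bins `floor((x - min) * L / (max - min))`, folding the single top value into
bin L-1; a constant image maps to all zeros, avoiding a divide-by-zero in
the range mapping. A `3sigma` mode maps mean ± 3 SD with tail clipping, and
`none` is a plain rescale from [0, 255]. 64 levels with min-max
normalization is the common texture-software default; quantization depth
matters mostly through the co-occurrence matrix size (L×L) and the scale of
level-difference features such as contrast. Normalizing per image also
makes all features invariant to adding a constant to every pixel.

## Texture features

**Co-occurrence (COM).** For each displacement (distance d in 1..5 at the
four principal angles 0°, 45°, 90°, 135°) the matrix accumulates each pixel
pair symmetrically, so counts equal their transpose and the sign of the
displacement is immaterial. Eleven Haralick-type features are computed from
the normalized matrix with gray levels indexed 0..L-1 and base-2 logarithms
(0·log 0 = 0): angular second moment, contrast, correlation, sum of
squares, inverse difference moment, sum average, sum variance, sum entropy,
entropy, difference variance and difference entropy. Sum variance is taken
about the sum average (the dominant modern convention). Correlation with a
zero-variance marginal is defined as 0 so feature vectors stay finite.
Features are averaged over the four angles at each distance —
rotation-robust aggregation that also quarters the descriptor count —
giving names like `com_d3_entropy`.

**Run length (RLM).** Maximal runs of identical gray level are tallied by
(level, length) along each of the four directions; single pixels are runs
of length 1, so runs partition the image and `sum(r · counts[g, r])` equals
the pixel count exactly (an invariant the tests enforce). Five features:
short- and long-run emphasis, gray-level and run-length nonuniformity, and
run percentage (runs per pixel). Features are averaged over the four
directions.

**Gradient (GRM).** Central differences on the *unquantized* 256-level
image, magnitude `sqrt((I[y+1,x]-I[y-1,x])^2 + (I[y,x+1]-I[y,x-1])^2)`
(absolute-gradient convention: the spacing of 2 is not divided out), border
pixels excluded rather than padded. Five features: mean, population
variance, skewness, excess kurtosis (both defined as 0 for a zero-variance
map) and the percentage of interior pixels with nonzero magnitude.

Total: 11 × 5 distances + 5 + 5 = 65 named descriptors per image.

## Fisher-coefficient selection

F = (between-class variance) / (within-class variance), computed with
group-size weights p_k = n_k/N and population (divide-by-n) group
variances; weighting matches the classical Fisher discriminant and handles
unequal image counts per group. A feature with zero within-class variance
and distinct means gets F = +inf and sorts above every finite value — a
perfectly separating feature must never be dropped; zero between- and
within-variance gives F = 0. Ties are broken by ascending feature name so
selection is deterministic. The default k = 10 reflects how many texture
descriptors remain informative at typical group sizes; the assay route
skips selection because all eight indicators carry independent meaning.
F is invariant under affine transforms of a feature, so selection commutes
with unit changes.

When a run clusters two reference groups plus one test group, F is computed
on exactly the groups present in that run (not the whole study), keeping
selection aligned with the clustering task at hand.

## Neural-network clustering

The classical binary threshold neuron (output 1 iff w·x > threshold, with
equality giving 0) is kept as a separately tested reference model; binary
threshold units cannot express distance-based cluster membership, so the
clustering itself is seeded winner-take-all competitive learning — a 1-D
Kohonen network without a neighborhood function, the canonical neural
clustering algorithm:

* features standardized to zero mean, unit SD (assay descriptors span
  orders of magnitude: catalase ~140 u/mg vs. MDA ~1 nmol/mg); zero-spread
  features are excluded from distances with a warning;
* units initialized at `n_clusters` distinct randomly chosen samples;
* each epoch visits samples in a fresh seeded random order; the nearest
  unit (Euclidean; ties to the lowest index) moves toward the sample by
  `eta(t) = eta0 · (1 - t/epochs)`;
* defaults: 2 clusters, 100 epochs, eta0 = 0.5. One hundred epochs with a
  linearly annealed rate is far past convergence for tens of samples; the
  final assignment is the nearest unit.

Training is bit-reproducible given (data, seed). On well-separated data the
learned 2-partition coincides with the exhaustive minimum-SSE 2-partition
(verified against an enumeration oracle at small n). Cluster indices are
arbitrary, which is why all reporting goes through canonicalization.

## Characterization

`cluster_distribution` reports, per group, the percentage of its samples in
each cluster, then relabels clusters so cluster 1 is the majority cluster
of the first reference group (the untreated control) and cluster 2 that of
the second (the toxicant-only group). If both references share a majority
cluster the raw indices are kept and a degeneracy flag is set.

The weighted average of a descriptor in a cluster is
`wa = (mu_d - mu_a) / mu_a`, with mu_d the cluster mean and mu_a the mean
over *all samples*. The all-samples reading of mu_a (rather than the mean
of cluster means) was chosen because it makes the mass balance
`sum_c n_c · wa_c = 0` exact for unequal cluster sizes — a checkable
invariant the tests hold to 1e-9. Descriptors with mu_a = 0 are flagged
undefined and excluded from plots.

## Synthetic data

**Animal tables.** Each group's eight indicators (testis and epididymis
weight, sperm count and motility, MDA, MPO, CAT, SOD) are drawn
independently per animal as Normal(mean, SE·sqrt(n)) from the printed group
summaries (n = 10) shipped in `data/group_defaults.yaml`; negative draws of
the physically nonnegative quantities are truncated at 0 with a logged
warning. The printed "±" is treated as a standard error (the source tables
are labeled mean ± SE); a `spread="sd"` option exists for the alternative
reading, which would triple the simulated spread. Covariances between
indicators are not published and are not modeled — simulated animals are
more "independent" than real ones, so pipeline results on these tables test
the machinery under the printed marginals, not the full joint biology.

**Texture images.** A tubule phantom: non-overlapping annuli (dark
epithelial wall, stippled cell lining, pale lumen) placed by rejection
sampling on a noisy background. The continuous degeneration level
delta ∈ [0, 1] models dose-dependent damage: stipple probability scales as
(1 - delta)·p_fill (germ-cell depletion), tubule count as (1 - 0.6·delta)
and wall radius as (1 - 0.3·delta) (atrophy without total disappearance),
and bright luminal vacuoles appear at a Poisson rate proportional to delta.
Pixel noise (SD 6 gray levels) is confined to stained tissue; lumina and
vacuoles are optically clear and stay flat, so the flat-area fraction — and
with it the gradient nonzero-percentage — carries morphological signal
instead of saturating. The default group schedule maps the study arms to
delta = 0 (control), 1 (toxicant only), 0.7 / 0.35 / 0.15 (low / medium /
high protective dose). The phantom reproduces the *spatial statistics*
contrast between intact and degenerated tissue (at default settings the
intact/degenerated classes differ by >5 pooled SDs on first-distance COM
entropy and on gradient nonzero-percentage); it is not photorealistic
histology — no staining color, no nuclei, no inter-tubular cell detail — so
passing tests demonstrate that the pipeline recovers class structure of
this kind, not that it would rank real dose groups identically.

All generators are pure functions of (parameters, seed); dataset generation
derives one child seed per image from a root seed sequence.

## Problem sizes and numerical choices

The end-to-end texture experiment uses 36 images per class at 256×256 px
(the study scale this package emulates used ~36 images per group; 744×744
rendering is available via the `--size` flag). Feature equivalence against
brute-force oracles is checked at 1e-10 on 16×16, 8-level images, where
exhaustive double loops are exact and fast. Clustering acceptance runs use
10 animals per group, matching the emulated design. Degenerate inputs are
handled by explicit conventions rather than NaNs: constant-image
quantization → zeros, zero-variance correlation/skewness/kurtosis → 0,
empty clusters and all-zero matrices → errors.

## Limitations

* The competitive-learning algorithm is a reconstruction of "neural network
  clustering" as commonly implemented; the original study's clustering
  software does not publish its algorithm, so exact per-sample membership
  percentages for intermediate dose groups are not expected to reproduce.
* Texture-route results depend on quantization depth and offsets; defaults
  are the field's common ones but the original analysis settings are
  unknown.
* Independent-normal animal simulation ignores indicator correlations.
* Only the three classical texture families are implemented; wavelet,
  autoregressive and histogram families are out of scope.
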