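# Methods

## Synthetic organoid generator

An organoid is a union of geometric primitives in micrometre
coordinates: capsules (thick line segments) for branches, disks for
cores, terminal end buds and cell clumps, and carved circular holes for
micro-lumens.  Because the geometry is explicit, every descriptor the
morphometry stage later measures — branch points, endpoints, end buds,
micro-lumen count/area, maximum Feret diameter — has an exact pre-noise
value recorded as ground truth.  Nine families are parameterized
(`archetypes.py`): trunk-built epithelial forms (TEBBO, thick branched,
tree-like), core-built forms (cystic branched, branched mesenchymal,
firework, star-like, clump), and a disconnected "scattered" form.  The
defaults place each family's defining feature prominently (bulbous end
buds of ~25 µm radius, four ~20 µm micro-lumens, a 240 µm near-circular
core for star-like organoids, a dozen thin radiating branches for
fireworks) at overall sizes of 280–930 µm, in the range reported for
collagen-gel organoids; thickness bands are kept distinct across
mesenchymal families so that the families remain geometrically
identifiable.  Per-organoid variability multiplies every parameter by
`1 + jitter·z` with `z ~ N(0,1)` truncated at ±2.5 (counts rounded,
with family-defining floors such as ≥3 branches for a star).

Branch placement enforces clearances so the design topology survives
rasterization: sub-branches attach away from terminal end buds by at
least the bud radius plus a margin across the divergence angle, spikes
sit midway between main-branch roots on the side whose neighbour tilts
away, and all sub-branches of a core-built family share one rotational
sense.  Rendering is brightfield-style: bright background (0.9), dark
organoid, multiplicative speckle inside the mask (sd =
`granularity_sigma`) emulating cytoplasmic granularity, Gaussian blur of
1 px, optional additive noise, clipped to [0, 1].  Default pixel size is
1.29 µm/px, recorded in every manifest.  Geometry that would not fit
the canvas raises an error; nothing is silently cropped.

The well-table, count-matrix and dose-response generators are direct
statistical simulators: binomial well outcomes under
`P(respond) = 1 − exp(−f·dose)` at the assay's 20/10/3/1 design;
negative-binomial counts (variance `µ + αµ²`, log-normal baselines
`exp(N(4, 1))`, uniform depth factors in [0.5, 2]) with disjoint blocks
of planted genes up-shifted by a known log2 fold change in one
phenotype only; and 4-parameter logistic viability over a 7-point
3-fold dilution series.

## Morphometry

Segmentation is Otsu's threshold on the 1-px-blurred image with the
dark phase as foreground (a fixed threshold is a config hook); objects
under 30 µm² are removed; connectivity is 8.  The skeleton graph is
built on the hole-filled mask (micro-lumens are measured separately as
topological holes) via Zhang thinning, with local radius from the
Euclidean distance transform.  Raw thinned skeletons of thick shapes
carry artefacts, so the graph is cleaned iteratively until stable:

* spurs hanging off a junction of local radius r are pruned when
  shorter than `max(10 µm, 1.5·r)` — thinning artefacts scale with
  thickness, real terminal branches are built much longer;
* degree-2 pass-through nodes are dissolved (edges concatenated);
* internal junction–junction edges shorter than
  `max(12 µm, 2·mean radius)` are contracted — they are medial-axis
  splits inside thick cores, not branches;
* components with no branch point and under 60 µm of skeleton are
  "blobs" (spheroids, debris) contributing no endpoints or nodes.

Descriptor conventions: major axis = maximum Feret diameter of the
mask (the straight-ruler analogue; computed across all components);
core thickness = twice the maximum distance transform (with lumens as
background, so a cyst wall measures as its tissue thickness); core
region = the connected part of `{DT ≥ 0.5·max DT}` containing the
argmax, and core circularity = its area over the area of the circle
spanned by its own diameter (≤ 1 by the isodiametric inequality; the
pixel-boundary Feret is corrected by 1 px).  A terminal end bud is an
endpoint whose local radius is ≥ 1.5× the proximal radius of its own
terminal branch (and ≥ 8 µm); a spiky branch is a terminal branch ≥
30 µm long and ≤ 0.55× the median branch radius.  Main branches are
counted off the trunk — the endpoint-to-endpoint path maximizing
∑ length·radius² — keeping trunk-incident branches at ≥ 0.5× the trunk
radius; for core-dominant bodies (circularity ≥ 0.6 and core diameter
≥ 80 µm on the filled mask) every branch crossing the core boundary
counts instead.  Granularity, visually graded at the bench, is
quantified as the intensity coefficient of variation inside the mask.
All thresholds live in `MeasureConfig` and are frozen by the test
suite.

The rule-based classifier is a fixed-order decision list (scattered →
clump → star-like → firework → branched mesenchymal → cystic branched
→ TEBBO → tree-like → thick branched → unclassified); order resolves
intermediate morphologies by declared convention, and each rule
reports the margin of its discriminating feature.  On the standard
320-organoid cohort (8 families × 40, jitter 0.1, noise-free) branch
point and endpoint counts are recovered exactly, major axes within
~1%, lumen areas within ~1.3%, and labels at >99% accuracy in ~1.5 min
on one CPU.

## Phenotype mapping

The classical feature backend concatenates the morphometric record
(counts log1p-compressed) with foreground intensity summaries and
z-scores each feature over the cohort; constant features are flagged
and zeroed.  The learned backend is a 3-conv-block CNN (8/16/32
channels, global average pooling, 64-d penultimate layer) trained with
Adam on softmax cross-entropy to classify a surrogate label — by
default the line identity (epithelial / mesenchymal / auxiliary) the
organoid grew from — on 64×64 inputs standardized per image; the
penultimate activations are then used as image features.  It is
implemented directly in numpy (im2col convolutions), so training is
bit-deterministic for a fixed seed; 20 epochs on a 200-image 2-class
task take about a minute on one CPU and reach perfect held-out
surrogate accuracy.  A ResNet-50 option exists as a config hook but
requires a deep-learning runtime.

Embedding is PCA (default 50 components, capped at the feature count)
followed by 2-D t-SNE (perplexity 30, PCA initialization, fixed seed).
Clustering is k-means (k-means++, 10 restarts) in feature/PCA space;
the t-SNE plane is for display and densities.  The number of clusters
comes from a Kneedle-style chord rule applied to the **log**-inertia
curve over k = 1..12: raw inertia is dominated by the coarsest split
(here the epithelial/mesenchymal superfamilies) and its chord knee
lands at 4–5, whereas the knee of the log curve sits at the finest
persistent scale, k = 8 across seeds for the 8-family cohort.  When
the whole inertia curve is consistent with the smooth power-law decay
of k-means on a single blob (log-log linear fit, R² ≥ 0.99), no elbow
exists and k = 1 is returned.  The inertia curve is always returned
for audit.

Density overlays are Gaussian KDEs per group on one shared grid
covering all points plus a 5% margin, renormalized to integrate to
exactly 1 on the grid; singular covariances fall back to an isotropic
kernel with a floored bandwidth.  Composition shifts are per-condition
percentage tables (rows sum to 100), Jensen–Shannon divergence in bits
against the control arm, and a chi-square test of homogeneity on the
raw counts.  Dose-response AUC is the trapezoid of viability over
log10 concentration normalized by the log-range (no effect ⇒ 1); GI50
is the log-linear interpolation of the first downward 0.5 crossing,
censored at the boundary concentration otherwise; z-scores across
clones use the population-sd convention, so a two-clone contrast gives
exactly ±1.

## Limiting-dilution potency

The single-hit model `P(negative | dose d) = exp(−f·d)` is fitted by
maximum likelihood as a binomial GLM with complementary log-log link,
log-dose offset and slope fixed at 1; the intercept is `log f`.
Potency is reported as "1 in x" with x = 1/f.  The default CI is Wald
on `log f` (symmetric in log space); a profile-likelihood CI is
available by inverting the likelihood-ratio test.  Boundary outcomes
(all or no wells responding) raise an explicit non-estimable error
with the boundary side rather than returning a number.  Zero-negative
and zero-positive dose rows stay in the likelihood without continuity
correction.  Single-dose tables reproduce the closed form
`f = −ln(F_neg)/d` to optimizer precision.  Model adequacy is a
likelihood-ratio test of free slope vs slope 1 on log dose; under
single-hit truth its type-I error at α = 0.05 is ~6% over 500
simulations of the 4-dose design at 50 wells/dose (200 wells total, the
bench design of ≥8 gels/density scaled up for calibration studies),
95% Wald coverage is ~97%, and power against a quadratic-dose
alternative `exp(−f·d²)` is ~100%.

## Signatures

Size factors are median-of-ratios against the geometric-mean reference
gene-wise.  Each one-vs-rest test fits, per gene, an NB log-linear
model with intercept, target indicator and log-size-factor offset.
The two group means have closed-form MLEs for this design; the NB
dispersion is then estimated by maximizing the Cox–Reid adjusted
profile likelihood (penalty −½ log det XᵀWX) on [1e-4, 10], and the
Wald statistic for the indicator comes from a GLM fit at that
dispersion.  BH adjustment is applied across genes; all-zero genes are
excluded and recorded.  There is deliberately no dispersion shrinkage
across genes and no fold-change moderation: the test is validated by
planted-gene recovery (Jaccard ≥ 0.8 per phenotype on the standard
3 × 3-replicate, 2000-gene, 50-planted design; in practice 1.0) and by
null calibration (BH-positive fraction < 1% on null data), not by
coefficient agreement with any DE package.  Signatures take genes with
BH-adjusted p < 0.05 and log2 fold change > +2 (up-regulation only),
thresholding first and then removing genes passing in more than one
phenotype (removals logged), so each signature is phenotype-private.

Activity scoring ranks a sample's genes by decreasing expression (ties
broken by fixed gene order) and integrates the recovery curve of
signature genes within the top `ceil(0.05·G)` ranks, normalized by the
maximum attainable area: 1 when the signature fills the top ranks, 0
when it is absent from the window, and invariant to any monotone
transform of the sample's expression.  The 5% window is configurable.

## What the synthetic data does and does not show

The generator provides exact, known answers for every stage, which is
what the tests exploit: geometric bookkeeping, statistical marginals,
planted-truth recovery, calibration of tests and intervals.  It does
not emulate uneven illumination, debris, touching organoids,
out-of-focus planes, photorealistic optics, 3-D structure or growth
dynamics, and its NB counts lack gene–gene correlation and
mean-dispersion trends.  Passing tests therefore demonstrate
correctness of the algorithms under controlled conditions, not
segmentation robustness on real microscopy; on real images the
thresholds in `MeasureConfig` and the classifier rule list are the
knobs to recalibrate.

## Problem sizes and determinism

Standard study conditions: 8 families × 40 organoids at jitter 0.1
(noise-free) for morphometry/mapping; 200 images, 2 classes for the
CNN surrogate task; 4 doses × 8 wells for a single assay and ×50 for
calibration studies (500 replicates); 3 phenotypes × 3 replicates,
2000 genes, 50 planted per phenotype at log2FC 3, dispersion 0.1 for
signatures.  Every random draw flows from an explicit integer seed;
the classical pipeline is reproducible bit-for-bit and the CNN
reproducible by weights hash.  `scripts/acceptance.py` re-runs all of
the above from one master seed in a few minutes on one CPU.
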