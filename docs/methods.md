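# Methods

This note records the models, numerical conventions and design choices behind
`lungmorph`, and what the synthetic-data experiments do and do not establish.

## Synthetic cohorts

`synthetic.CohortSpec` defines the study conditions. Defaults emulate a
LUAD/LUSC cohort of 525 + 727 patients. Per-patient nucleus counts follow a
gamma–Poisson (negative binomial) with mean 210 and dispersion 5, putting the
median near 200 — the balancing target — with roughly half the patients below
it. Overall survival is exponential per class (median ≈ 4.1 years for
class 1, ≈ 3.0 years for class 2, in the range reported for resected NSCLC
cohorts) with independent uniform censoring over an 8-year follow-up window;
this is the simplest model whose event fractions at the 1/2/3-year horizons
are controllable in closed form. Clinical categories are drawn from the
encoded vocabularies with frequencies loosely matching public NSCLC cohorts;
CNV amplitudes are gamma-distributed; SNV classifications are sampled from
the non-synonymous/synonymous vocabularies; mRNA is Gaussian per gene on a
log-expression-like scale.

Nuclei are rendered as filled, non-overlapping ellipses (rejection sampling
with a 1-px margin) over a noisy pale background with a per-tile stain shift;
this gives analytically known area, axes and eccentricity for oracle tests.
Placement failures are reported (`placed < requested`), never silent.

`sample_feature_rows` is the fast tabular arm: it draws the 20 feature
columns directly as unit-variance Gaussians with a per-patient random
intercept (SD 0.3) modelling within-patient correlation, plus configurable
between-class mean shifts. It deliberately skips rendering, so experiments at
hundreds of patients run in seconds.

What this does **not** emulate: real H&E texture, touching/overlapping
nuclei, staining artefacts, segmentation-error-correlated features, batch
effects, or realistic gene–gene covariance. Passing tests therefore establish
the pipeline's correctness and its ability to recover planted signal under
the stated noise model — not clinical performance on real cohorts.

## Image preparation

Tiles are cut on a 0-based row-major grid from the top-left origin; edge
remainders are dropped rather than padded so all tiles share one size
(default 1024 px; the synthetic examples use 64–128 px). The blank rule —
a pixel is near-white when all channels ≥ 220, a tile blank when > 90% of its
pixels are near-white — is an explicit, configurable convention; an all-black
tile is *not* blank because the rule targets unstained background.
Histogram matching is per-channel in RGB (the downstream colour features live
in RGB), implemented by the empirical-CDF/quantile mapping; it is the
identity for self-matching and idempotent up to 8-bit quantisation.

## Segmentation

The segmenter is a deliberately small U-shaped encoder–decoder written in
NumPy: one 3×3 convolution + ReLU per block, 2×2 max-pooling, nearest-
neighbour upsampling with skip concatenation, a 1×1 sigmoid head; He
initialisation, Adam (lr 3e-3), per-pixel binary cross-entropy; fully
deterministic given the seed. Default depth 2 and 8 base channels train on
forty 64-px synthetic tiles in ~15 s on one CPU and reach held-out Dice
≈ 0.97 against the generator's true masks; depth/width/epochs are
configurable for larger problems. Checkpoints are NumPy archives.

Instance conventions, fixed for reproducible counts:

- Foreground = probability ≥ 0.5 (configurable); components 8-connected.
- Perimeter = arc length of the outer-boundary polygon through boundary
  pixel centres (Moore-neighbour tracing; axial step 1, diagonal √2); a
  single pixel has perimeter 1 by convention. Tracing terminates at the first
  repeated (pixel, backtrack) state — a criterion that also closes the cycle
  on 1-px-wide regions where the classical same-entry-direction rule loops.
- This chain-code estimator overestimates smooth contours by 3–5%
  (rasterisation study: digital discs of radius 10–60 have circularity
  0.92–0.98, converging downward), and pixel-centre polygons underestimate
  very small shapes. Both biases are properties of the documented estimator
  and are consistent across all features using *P*.

The quality filter computes Otsu thresholds on the per-image histograms of
area and compactness (64 equal-width bins over the observed range).
Comparisons are strict — removal requires *A* strictly below or *C* strictly
above its threshold — so boundary-equal instances are kept. A degenerate
feature (all values identical) skips that criterion and is logged; the other
still applies. Otsu ties (splits moving across empty bins leave the
between-class variance mathematically unchanged) resolve to the smallest
edge via a 1e-9 relative tolerance; bit-level argmax would otherwise pick an
arbitrary plateau point set by float summation noise. Note the filter
*always* splits each image's population: on a tile of uniformly good nuclei
it still removes the smaller/raggeder fraction. This adaptivity is the
method's stated behaviour, not an artefact.

## Nuclear features

The 20 columns, in fixed order: R/G/B means, R/G/B population variances
(computed on the histogram-matched tile, over nucleus pixels only); Area;
Perimeter; Circularity 4πA/P²; Compactness P²/A (their product is 4π
identically); Eccentric; Hu0–Hu6; cD_average, cD_var.

Moments use the image convention (x = columns, y = rows), normalised central
moments η_pq = μ_pq/μ00^γ with γ = (p+q)/2 + 1. Hu invariants are computed
on the **binary silhouette** (they are grouped with the morphology features),
cropped to its bounding box first — translation invariance is then bit-exact
because a translated shape yields the identical cropped array. Rotation and
scale invariance hold to raster tolerance (90° rotations to machine
precision). The widely-reproduced typographic corruptions of the 5th and 7th
invariant formulas in secondary sources are avoided; the standard forms are
used, and skimage's implementation serves as an independent cross-check in
tests (its row/column axis convention is a reflection, flipping the sign of
the seventh invariant only).

Eccentricity comes from the moment-equivalent ellipse: with λ1 ≥ λ2 the
eigenvalues of the second-central-moment matrix divided by μ00,
E = √(1 − λ2/λ1). Degenerate (line-like) regions clamp λ2 at a small
positive value and stay in [0, 1).

Texture is a single-level 2-D DWT, Haar by default, of the grayscale
(Rec. 709 luminance) bounding-box patch with non-nucleus pixels zeroed;
cD_average/cD_var are the mean and population variance of the diagonal
subband. Periodised boundary handling makes the transform equal the plain
decimated two-step filter bank (g = (1,1)/√2, h = (1,−1)/√2) on even-sized
patches. Whether the statistic is computed per nucleus (default) or per tile
is a configuration option (`scope`), since either reading is defensible;
per-nucleus keeps the feature a property of the nucleus row. Variances are
population (divide by N) throughout.

## Factor encoding and dataset assembly

Encodings: sex 1/2; race 0 (unreported) to 4; T and N 1–4 with X as 5;
M 1/2 with X as 5; stage 1–4. Survival horizons are 365/730/1095 days.
The three-class survival label keeps "unknown" (alive, censored before the
horizon) as class 0 in both training and evaluation; a flag can exclude it.
CNV boundary amplitudes (t exactly 0.1 or 0.9) go to the lower class — the
published open intervals leave boundaries undefined, so the tie rule is
explicit. SNV classification is a closed vocabulary; an unlisted spelling is
a validation error, never silently synonymous.

The gene panel is the 27 genes recurrently mutated in both subtypes. The CNV
and mRNA sub-panels default to the published factor-schema sizes (15 and 26);
which genes drop (the published criterion, "factors with values of zero", is
not recomputable from the tables alone) is a configuration input, defaulting
to the leading genes of the panel. Schema widths: subtype 20+26 = 46;
survival 20+7+15+27+26 = 95.

Balancing is exactly 200 rows per patient (uniform subsample above, originals
plus uniform duplicates below). Splitting is by patient — no nucleus of a
test patient is ever seen in training — and stratified by subtype by default:
the published per-subtype training counts (315/437 of 525/727) equal exact
60% strata, which unstratified splitting reproduces only by accident. Within
a stratum, validation and test sizes are round-half-up of f·n and train takes
the remainder; this reproduces 752/250/250 overall and implies the held-out
composition 105 LUAD + 145 LUSC per split (the published prose swaps these
two numbers in a way inconsistent with its own totals; the arithmetic is
followed).

## Screening

Pearson r with the numeric-coded label, p from the exact t-statistic with
n−2 degrees of freedom; retained iff |r| > 0.05 and p < 0.05. Screening runs
on the training partition only, at nucleus-row level by default (a
patient-mean aggregation flag exists), avoiding test leakage. Constant
factors are reported as degenerate, never silently dropped. The factor–factor
correlation matrix is exported with |r| > 0.8 pairs flagged, optionally as a
heatmap PNG.

## Model evaluation

Required families: LightGBM, XGBoost, random forest, AdaBoost, MLP.
Tabular-attention and 1-D CNN slots exist behind the same adapter interface
and are reported as skipped when no adapter is registered. Search spaces
default to the published candidate grids; the AdaBoost boosting-variant axis
is omitted because current scikit-learn implements only the discrete SAMME
algorithm. Tuning maximises validation accuracy (deterministic given seeds;
ties to the first configuration in sorted enumeration order) with either
exhaustive grid or seeded random sampling under a trial budget — the full
grids (e.g. 1800 LightGBM configurations) are impractical per experiment, so
the default strategy samples a seeded subset.

Metrics: global accuracy; binary precision/recall/F1 with the larger class
label as positive; macro one-vs-rest averages for three-class survival, with
classes absent from the truth excluded from the macro mean and logged. AUC is
trapezoidal integration of the ROC, equal to the Mann–Whitney rank statistic
(ties counted half); multiclass AUC is the macro mean of one-vs-rest AUCs.
Predictions are evaluated per nucleus row (matching the record-level dataset
construction); fit wall-clock duration is logged but hardware-dependent and
never asserted. The test partition is materialised once per family, after
tuning, and the access log records it.

## Desk-scale experiment sizes

The test suite and the acceptance script use reduced problem sizes chosen to
exercise every code path with comfortable statistical margins: 64-px tiles,
50-tile segmentation sets (40 train / 10 held out, 15 epochs), 24-patient
screening cohorts × 100 replicates, and 200-patient modelling cohorts with
40–60 rows per patient and random-search budgets of 2–6 trials. The
cohort-construction arithmetic alone runs at the full 1252-patient count,
with the tabular feature sampler standing in for rendered images.

Two statistical facts shape the recovery experiments. First, with
patient-constant genetic columns in the design, record-level test AUC
effectively has the test *patients* (not rows) as its sample size; on
200-patient null cohorts its replicate SD is ≈ 0.09, so chance-level
behaviour is asserted on the mean over independent replicate cohorts rather
than per replicate. Second, planted per-row effects of 1.5 SD on four shape
features put boosted trees at test AUC ≈ 0.95 across seeds, well clear of the
0.9 recovery bound.

## Known limitations

- No whole-slide (pyramid) reader: the pipeline ingests plain PNG/TIFF
  images; level 0 of a pyramid must be exported upstream.
- No touching-nucleus splitting (watershed etc.); the synthetic renderer
  enforces non-overlap, so the segmenter is not tested on merges.
- The NumPy U-Net is sized for desk-scale tiles; training full-size
  1024-px tiles would need the configurable larger geometry and patience.
- Stain normalisation is histogram matching only (no stain deconvolution).
- The adaptive quality filter always removes part of every image's instance
  population; images with uniformly good nuclei lose their lower tail.
- Correlation screening is univariate Pearson on ordinal-coded factors;
  rank-based and model-based importance screening are out of scope.
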