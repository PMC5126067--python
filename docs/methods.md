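# Methods

This note records the models, conventions and design decisions behind
`phenomet`, in the spirit of a statistical methods appendix: what each
stage assumes, which knobs matter, and what the synthetic benchmarks do
and do not demonstrate.

## Image segmentation and feature extraction

Segmentation is purely rule-based in 8-bit RGB space; there is no learned
component.  The three pixel classes are conjunctions of channel
inequalities (see README), evaluated exactly:

* **Yellow** — `V_R − V_G ≥ 10`.  "Ten levels higher" is read as an
  inclusive threshold: a pixel whose red channel is exactly 10 levels above
  green is yellow.  The threshold is a `TrayLayout` parameter.
* **Grey** — four strict inequalities on `V_G/V_B`, `V_G/V_R` and `V_G`.
  Zero-valued red or blue channels would make a ratio undefined; such
  pixels are defined not-grey rather than propagating NaN.
* **Top-view plant** — seven strict inequalities.  A zero blue channel is
  treated as ratio +∞, so `V_G/V_B > 1.5` passes whenever green is
  positive (the `V_G > 20` term already excludes black pixels).

Yellow and grey are *not* disjoint (e.g. (120, 110, 70) satisfies both);
the counts are reported independently because they are separate stress
indicators, not a partition.  The side-view plant rule is the union of all
three classes, so senescent tissue counts toward projected area and the
color counts are subsets of the plant mask; the rule is injectable for
cameras with different color geometry.  Whether "total pixels" should
instead exclude senescent tissue is genuinely ambiguous in the field; the
inclusive reading is the default and the alternative is one lambda away.

Coordinates: row 0 at the image top, heights in rows, the ROI bottom row
(the baseline just above the pot) inclusive.  Height is the row span from
the baseline to the topmost mask pixel; an empty mask has height 0.

The separating panel is found as the maximal run of columns (and rows, for
the top-view cross) in which at least half the pixels match a reserved
saturated-blue band that fails all three plant classifiers; the run's
midpoint is the panel center and its edges bound the per-plant ROIs.
Configured fallback coordinates take over, with a warning, when no panel
is found.

Noise suppression removes 8-connected components of area ≤ 20 px.  The
scale comes from the observation that background patches passing the color
rules cluster around 10–20 px; 8-connectivity is the standard
conservative choice for thin diagonal structures.  Components of 21 px or
more are preserved pixel-for-pixel — the filter never erodes.

Scene normalization (the stand-in for camera-side filtering) is identity
by default.  Two optional corrections are provided: grey-world white
balance, and a luminance correction that shifts each channel's mode (the
dominant background level) to a configured reference, which exactly undoes
global additive offsets.  Local contrast equalization was considered and
rejected: the classifiers are exact inequalities, and spatially varying
remapping perturbs counts unpredictably near class boundaries.

## Drought-screen statistics

`PWC (%) = (FW − DW)/FW × 100` with domain guards `FW > 0`,
`0 ≤ DW ≤ FW`; the statistic is invariant to rescaling both weights.
Tolerance classes use strict outer inequalities — TOL iff PWC > 70, SUS
iff PWC < 55 — so both boundary values fall in the closed intermediate
band [55, 70].  Thresholds are parameters.

The PWC–wilting correlation is computed on ecotype means, not replicates:
the scientific claim is about the agreement of two ecotype-level rankings,
and replicate-level correlation would conflate within-ecotype measurement
noise with the between-ecotype signal.  Constant vectors raise rather than
returning NaN.  Ties in the PWC ranking break alphabetically by ecotype
id, making the output order deterministic.

## Growth curves

Normalization divides each plant's series by its value on the baseline day
(default 34 das, the first imaging day); the operation is idempotent and
makes curves camera-zoom invariant.  "Biomass accumulation during the
treatment" is defined as normalized final value minus one — the simplest
functional of the curve that is monotone in growth and dimensionless.
Treatment contrasts aggregate per-plant gains to per-ecotype means first,
then compare treatment means over the matched ecotype panel; the yield
penalty of treatment *a* against reference *b* is `1 − mean(a)/mean(b)`.
Whether per-plant or per-ecotype aggregation is used first changes the
weighting when replicate counts differ; per-ecotype-first is the default
because panels are the unit of comparison.

## FIE-MS preprocessing and screening

Order is fixed: low-mass filter (default m/z < 50, where electrospray
noise dominates) → total-ion-count normalization (each intensity becomes a
percentage of its sample's remaining total, so rows sum to exactly 100) →
statistics.  An optional log transform is available but off by default.
One-way fixed-effects ANOVA runs per feature via vectorized sums of
squares with p from the F distribution; degenerate inputs follow explicit
contracts (zero between-group variance → F = 0, p = 1; zero within-group
variance with real differences → F = ∞, p = 0).  Raw p-values are the
default; Benjamini–Hochberg q-values are optional because no particular
correction is canonical for exploratory FIE-MS screens.  Pathway m/z
targets match their nearest feature within a tolerance (default 10 ppm;
absolute Daltons available for nominal-mass data); equidistant ties take
the lower mass.

**Closure caveat.**  TIC normalization is compositional: a genuine class
effect planted on some features mechanically shifts the normalized values
of *all* features (the row must still sum to 100).  Consequently "the
planted features have the smallest p-values" is only a theorem *before*
normalization, and the package's power benchmark is run on raw matrices.
Under the null there is no class shift to redistribute, so the false-
positive calibration of the screen is unaffected by normalization.

## Multivariate integration

Autoscaling z-scores each column using the population SD (divisor n), the
standard-scaler convention, giving exactly unit-variance columns;
constant columns either raise (naming the offenders) or are dropped and
logged.  PCA is computed on the autoscaled matrix with a deterministic
sign convention (each component's largest-magnitude loading is positive).
Per-class 95% confidence regions are circles in the PC1–PC2 plane:
center at the class centroid, radius `sqrt(chi2_{2,0.95})` times the RMS
within-class distance of scores to the centroid.  Circles (not Hotelling
ellipses) are used because the regions are summaries for a separation
verdict, not inferential contours; the radius convention is deliberately
conservative (it treats the full planar RMS as the per-axis scale).  Two
classes "separate" when their circles have zero overlap area; the report
carries pairwise centroid distances and overlap fractions (lens area over
the smaller circle) so the verdict can be re-derived under any other
convention.

Hierarchical clustering uses `d = 1 − r` between row profiles with
average linkage by default (the common chemometrics default; single and
complete linkage are available).  Correlation distance is invariant to
per-row positive affine transforms, which is the property that makes it
appropriate for profiles on arbitrary intensity scales; its blind spot is
that a profile proportional to the grand mean has no direction, which is
why constant rows raise immediately.

Block correlation joins phenotype and metabolite blocks on shared row
keys, autoscales the union, and computes the full Pearson matrix.  Each
variable is reported with its correlation and sign against an anchor
variable (default `area_side`, the biomass proxy), which is how
"metabolite X rises with biomass and falls with senescence" becomes a
checkable sign pattern.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *geometry and statistics* the pipeline
depends on, not the appearance of plants:

* **Tray images** — plant silhouettes are unions of bottom-anchored
  rectangles with exact pixel areas and heights, drawn in reserved colors
  that provably satisfy exactly one classifier each; the panel is a
  saturated-blue band that fails all of them; noise patches are 10–20 px
  8-connected blobs in a plant color, placed with a 1-px guard band so
  they can never merge with a silhouette.  Image size defaults to
  640 × 480 (side) and 640 × 640 (top); resolution is an arbitrary
  parameter, not a claim about any camera.
* **Screen tables** — replicate PWC is Gaussian around per-ecotype means
  (default linspace 30–80%, matching the span seen in real diversity
  panels); dry weights are uniform in 0.18–0.32 g (the range typical of
  well-watered grass shoots at harvest) and fresh weight is back-computed
  so PWC is exact by construction.  Wilting is a latent linear function of
  PWC (`1 + slope·(100 − PWC) + ε`) rounded and clipped to the ordinal
  1–6 scale.  `ScreenSpec.for_correlation` solves the latent noise SD in
  closed form for a requested ecotype-level correlation; rounding and
  clipping attenuate the realized |r| by a few hundredths, a bias that is
  documented rather than corrected.
* **Metabolomes** — per-feature log-normal bases spanning three decades,
  log-scale noise (default σ = 0.1), and multiplicative class effects on
  designated features, plus sub-50 m/z features to exercise the filter.
  Two effect layouts exist: *shared* (all responding classes scale the
  same feature set — the right null/power benchmark for univariate
  screening) and *blocks* (each responding class elevates its own feature
  block — the geometry needed for three classes to be mutually
  distinguishable by correlation distance, as real tolerance groups are
  via their distinct pathway signatures).  The severe-drought scenario
  uses blocks with fold 8 and the matched control sets all folds to 1.
* **Growth tables** — linear area trajectories over 34–45 das with
  treatment-mean gains 0.60 (75% SWC control), 0.372 (15% SWC mild) and
  0.201 (0% SWC severe), chosen so the built-in mild-vs-severe extra
  accumulation is 85% and the mild-vs-control yield penalty is 38%.
  Per-ecotype gain variability is kept small (CV 0.05) so these panel
  means are identifiable at the study scale of 9 ecotypes; real panels
  show far wider per-ecotype spread, so the benchmark validates the
  contrast arithmetic, not biological variability.

Passing these benchmarks shows the pipeline is *correct* — classifiers
match their definitions, features are recovered pixel-exactly, statistics
are calibrated and planted structure is found.  It does not show
robustness to real-image nuisances (shadows, specular highlights, leaf
overlap between neighboring plants, soil pixels inside the canopy), which
rectangles with reserved colors cannot represent.

## Problem sizes and numerical conventions

Benchmarks run at the scale of the emulated study: 48-ecotype screens
with 6 replicates, 9-sample (3 × 3) metabolomes with 120 + 10 features,
9-ecotype growth panels, 50-tray image batches, and 200-replicate
simulations for calibration rates.  TIC row sums are exact to 1e-9
relative; ANOVA F is checked against independent oracles at 1e-10
relative; autoscaled columns are zero-mean/unit-SD to 1e-9; PCA
reconstruction from all components is exact to 1e-8.  All generators and
analyses are deterministic given their seeds; the acceptance script
derives every sub-seed from the single `--seed` argument.
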