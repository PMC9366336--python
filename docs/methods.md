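# Methods

This note documents the models, numerical choices and limitations of
`bametrics`. It is written for a reader who wants to know *why* the package
computes what it computes, and what passing its tests does and does not
establish about real data.

## Vessel geometry

### Centerline model

The basilar artery is represented by an ordered polyline in world
millimetres connecting four annotated landmarks (basilar apex → AICA origin →
vertebral fusion → PICA origin, the caudal annotation order). Extraction has
three stages:

1. **Minimal-cost path.** Voxels with normalized intensity ≥ 0.5 form the
   lumen graph (26-connectivity). Normalization maps the volume's 50th
   percentile (background; vessels occupy a small volume fraction in ToF
   angiography) to 0 and the 99.9th to 1, clipped — so every subsequent
   criterion is invariant to affine intensity rescaling. Edge cost is the
   physical edge length times (ε + 1 − mean endpoint intensity), ε = 0.05,
   which keeps the path inside the bright lumen without a vesselness filter.
   Dijkstra runs between consecutive landmark pairs; nodes are laid out in
   lexicographic voxel order so ties resolve deterministically. A landmark
   whose neighbourhood (one voxel diagonal) contains no lumen voxel raises a
   "landmark in background" error; an unreachable pair raises "disconnected
   vessel".
2. **Smoothing and resampling.** The raw digital path overestimates length
   (staircase bias, up to ~8% on oblique runs). It is resampled at 0.25 mm,
   moving-averaged over a 2 mm window (window shrinks at the ends so
   endpoints stay fixed), and resampled at 0.5 mm.
3. **Lumen recentring.** Minimal paths cut the inside of bends because cost
   is flat across the bright lumen core; on helical phantoms this leaves
   +1–3% length error. Each path point is therefore replaced by the center
   of the circle fitted to its own cross-section (two passes at the contour
   spacing, each followed by a 1 mm moving average — circle centers carry
   noise, and the occasional bad fit at a tight bend, that would otherwise
   inflate the arc length). On phantoms this puts the polyline within
   ~0.02 mm RMS of the analytic centerline. Landmarks are finally attached
   by inserting each landmark point into the polyline at its orthogonal
   projection locus; the path then passes through every landmark, so the
   integral length between two landmarks can never fall below their
   straight-line distance.

Integral branch length is the arc-length difference between attachment
points; it is symmetric, zero for a degenerate pair, and can only exceed or
equal the landmark chord.

### Lumen contours and diameter

At each sample position (every 0.5 mm along the branch) the plane orthogonal
to the local tangent is probed on 32 radial rays (0.1 mm steps, trilinear
interpolation). The boundary on a ray is the first crossing of the
full-width-half-maximum level — half the local centerline intensity over
background, both in normalized units. A contour is *invalid*, not an error,
if fewer than 60% of rays find a boundary (e.g. the vessel leaves the field
of view) or if the circle-fit residual RMS exceeds 0.3 mm. Circles are fitted
by Pratt's algebraic least squares (exact on noiseless circles; collinear
input is rejected). The branch diameter is the median over valid contours;
if more than half the contours are invalid the branch raises an "unreliable
diameter" error that carries the partial result.

Expected accuracy at ToF-like spacing (0.357 × 0.357 × 0.5 mm), radii
1.2–1.8 mm, blur σ = 0.3 mm: length within ~0.2% of quadrature truth,
median diameter within ~0.09 mm (a small negative bias, ≈σ²/r, from blur
acting on the curved boundary — well inside the 0.15 mm test tolerance).
Radii below twice the coarsest voxel dimension set a resolvability warning
on the phantom truth record. Two rendering details matter for fidelity: the
tube boundary is rasterized through a one-voxel linear partial-volume ramp
(a hard threshold leaves the half-max radius quantized to the lattice by
±0.1 mm), and the tube continues tangentially past both curve ends so branch
endpoints do not sample an artificial end cap.

## WMH detection and regional mapping

Candidate lesions are outliers of a full-covariance Gaussian mixture on
(T1, FLAIR) pairs within the brain mask; the component count is chosen by BIC
over 1–6 components (fitted on a 30 000-voxel subsample, fixed internal
seed). A voxel is a candidate when its Mahalanobis distance to every
component exceeds 3 *and* its FLAIR value lies above the mean of its closest
component (the hyperintense side). Connected components (26-connectivity)
smaller than 5 voxels are dropped; when a depth map is supplied, components
whose centroid has normalized depth > 0.95 are dropped as cortical-surface
artifacts. This is a deliberately simplified stand-in for full
lesion-segmentation frameworks: it preserves the logic (mixture outliers +
location-based filtering) at a scale where every step is testable against
seeded truth.

Depth is d = d_v/(d_v + d_c) with both distances Euclidean in mm
(anisotropic voxels respected); layer k covers d ∈ ((k−1)/4, k/4], d = 0 in
layer 1. Voxels inside the surface masks receive the clipped limit so layers
are defined everywhere, but only the strictly-between band enters partition
properties. Lobe assignment is nearest labelled cortical voxel (Euclidean in
mm); "parieto-occipital" is the union of the parietal and occipital labels.
Because each lesion voxel lands in exactly one lobe × layer cell, the
regional matrix sums to the total by construction, with no tolerance.

## Cohort simulation

The generator reproduces the study's sampling frame: three ethnic groups
(EU, SA, AC), 120 participants each, with group-specific covariate
distributions taken from the published demographic table — normal for
continuous covariates (mean/SD as printed), Bernoulli for prevalences,
categorical for the Circle-of-Willis variant (printed frequencies). Outcomes
printed as median [IQR] are modelled as normal (vessel markers; SD =
IQR/1.349) or log-normal (WMH volumes; log-scale parameters matched to the
printed quartiles).

Outcomes follow a linear truth model on centred covariates, so group-level
locations stay at their published values regardless of planted slopes. WMH
outcomes are generated log-normally so the downstream log-linear model is
correctly specified. WMH outcomes may additionally depend on the vessel
markers — the large-vessel/small-vessel association under study — which is
how partial-correlation recovery tests plant a known effect. The three
regional WMH volumes are drawn per-region (frontal + parieto-occipital is
not constrained to the total); only the marginal models use them, so this
does not bias any fitted quantity.

Missingness is applied after generation, missing-at-random conditioned on
observed age (logit-linear in standardized age, intercept solved so the
marginal rate matches the requested fraction) — matching the assumption of
the imputation model. Default rates (5% cholesterol/HDL, 3% education, 2%
BP) are modest, as in clinic-collected covariates; the study's own
missingness summary is not publicly available.

Noise calibration: the published +11.3 μm/year diameter-age slope comes with
a 95% CI of [3.05; 19.62]; inverting the single-covariate CI-width formula
(half-width = t·σ/(SD_age·√n)) gives a residual SD of ≈0.275 mm, which is
also consistent with the printed marginal IQR of the diameter. This
conflates sampling and imputation variance — the paper's CI includes both —
but is the only calibration the printed numbers support.

All generators draw every random quantity from a single integer seed per
call; no global state is read or written.

## Statistical analysis

* **Group comparisons**: Pearson chi-square without continuity correction
  (categorical), one-way ANOVA (continuous), ANCOVA type-II F for group
  after a-priori covariates (imaging variables). Pairwise two-group
  analogues run only when the omnibus p < 0.05, uncorrected — multiplicity
  correction is deliberately absent throughout, as in the study design.
  Expected cell counts below 5 produce a warning, not an error.
* **BP correction**: +10/+5 mmHg (systolic/diastolic) for participants on
  antihypertensive medication; element-wise, missing values propagate.
* **Multiple imputation**: chained equations with predictive mean matching
  (5 donors), 10 sweeps, m completed tables. Regression parameters are drawn
  from their approximate posterior (inverse-chi-square variance, normal
  coefficients), giving proper-enough imputations while PMM keeps binary and
  categorical values in their observed support with a single sampler. Each
  of the m chains gets an independent child of the caller's seed; observed
  values are never altered. Variables more than 40% missing are refused.
  (statsmodels' MICE draws from the global RandomState and does not expose
  the per-table access this pipeline needs, so the sampler is implemented
  here; statsmodels still does all model fitting.)
* **Pooling**: Rubin's rules with Barnard–Rubin degrees of freedom; with no
  between-imputation variance (including m = 1) the pooled result equals the
  single fit exactly.
* **Effect sizes**: Cohen's D per covariate from the pooled t statistic,
  d = 2t/√df_resid — the standard t→d conversion; the source figures define
  no formula, and this reproduces sign and relative magnitude without
  standardized-coefficient ambiguity.
* **Percent effects**: log-scale WMH coefficients reported as
  100·(e^β − 1) percent per covariate unit (so β = 0.0840 per year reads as
  +8.76%/year); the inverse transform is provided and round-trips exactly.
  Whether the source's printed percentages used e^β − 1 or β directly is not
  stated; this package commits to the former.
* **Partial Spearman**: rank x, y and continuous covariates (average ranks),
  leave binary covariates and categorical dummies unranked, residualize the
  ranks on each side's covariate design, and correlate the residuals. With
  no covariates this reduces exactly to plain Spearman. Pooling across
  imputations is by mean Fisher z (the design is silent; Fisher-z averaging
  is the standard choice), p from the t approximation with
  df = n − 2 − #covariates. Rank-then-residualize was chosen over
  residualize-then-rank as the standard partial-Spearman estimator; the
  no-covariate oracle equivalence pins the convention.
* **Model 1 / Model 2 grids**: Model 1 adjusts the vessel side for age, sex,
  height and CoW variant and the WMH side for age, sex and TIV; Model 2 adds
  smoking, diabetes, lipids, both blood pressures, both medications, stroke,
  CHD and education to both sides; 2 markers × 3 regions × 2 models = 12
  results per group.
* **Degenerate covariates**: a covariate that is (near-)constant within a
  group — e.g. zero or one stroke case among 120 — is dropped from that
  group's model with a warning; a genuinely collinear user-supplied design
  still raises an error naming the columns.

## Problem sizes and runtimes

Tests and the acceptance script are sized for a single CPU: tube phantoms
are ~50 mm vessels on grids of ≲0.5 M voxels (seconds each); the brain
phantom is 72 × 88 × 72 at 1 mm (mixture fit on a 30 k subsample, ~1 s);
null-calibration runs use 400 simulation seeds at m = 1 on complete data
(regressions on complete data are invariant to the imputation seed), and
slope-recovery runs 400 seeds at m = 20 — m = 200, the design value, changes
pooled estimates negligibly at these missingness rates while scaling runtime
linearly. The CI-coverage check uses 400 seeds because a 200-seed binomial
estimate of a 95% rate has a standard error of 1.5%, uncomfortably close to
the ±3-point tolerance it is compared against.

## What the tests do and do not show

Phantoms exercise the geometric estimators under partial volume, blur,
noise and anisotropy, with analytic truth — but not flow artifacts, bias
fields, oblique acquisitions, vessel wall irregularity or annotation error.
The lesion model tests detection and regional accounting, not the
appearance-based artifact classification or dynamic model selection of full
segmentation frameworks. The cohort simulator makes the analysis model
correctly specified by construction; recovery and calibration results
therefore validate the *implementation* of the estimators, not the
correctness of the published substantive findings. Fetal Circle-of-Willis
variants enter only as a categorical covariate; their geometry is not
simulated.
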