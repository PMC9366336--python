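# bametrics

Quantification pipeline for **early vascular aging (EVA) of the basilar
artery** and its association with **cerebral small vessel disease**, built to
run end-to-end on synthetic phantoms and simulated cohorts.

Risk of stroke and dementia differs markedly across ethnic groups, and
accelerated remodelling of cerebral arteries — dilation and elongation beyond
chronological age — is one candidate mechanism. This package implements the
three quantitative stages such a study needs:

1. **Vessel geometry** (`bametrics.vessel`) — given a ToF-MRA-like volume and
   four annotated landmarks (basilar apex, AICA origin, vertebral fusion,
   PICA origin), extract a minimal-cost centerline over the bright lumen,
   and report per branch the *integral length*

   L(a,b) = ∫ₐᵇ ‖c′(s)‖ ds

   (arc length of the centerline c between landmarks, not the chord), and the
   *median diameter* — the median of radii from Pratt least-squares circle
   fits to luminal contours sampled every 0.5 mm in planes orthogonal to the
   centerline, with the lumen boundary located at the full-width-half-maximum
   criterion on 32 radial rays.

2. **WMH regional load** (`bametrics.lesions`) — detect white-matter
   hyperintensities as FLAIR-hyperintense outliers of a BIC-selected
   two-channel Gaussian mixture on (T1, FLAIR), then aggregate lesion volume
   by *closest cortical lobe* × *four equidistant depth layers* of the
   normalized ventricle-to-cortex distance d = d_v/(d_v + d_c), reporting
   total, frontal and parieto-occipital loads in mL.

3. **Stratified cohort statistics** (`bametrics.stats`) — the study's
   analysis design: chi-square / ANOVA / ANCOVA group comparisons with
   uncorrected pairwise contrasts gated on the omnibus test; +10/+5 mmHg
   blood-pressure correction for treated participants; multiple imputation by
   chained equations (predictive mean matching, m = 200 by design) pooled by
   Rubin's rules; per-ethnicity linear regressions of each marker on the
   Framingham covariates plus diastolic BP, medication, history, scale and
   Circle-of-Willis variant, with Cohen's D = 2t/√df per covariate; log-scale
   WMH models reported as percent change 100·(e^β − 1); and covariate-adjusted
   partial Spearman correlations (rank → residualize → correlate, Fisher-z
   pooled) between vessel markers and WMH regions.

Because the underlying cohort data are access-restricted, the package ships
first-class generators (`bametrics.phantoms`, `bametrics.cohort_sim`): curved
tube phantoms with closed-form length/diameter truth at ToF voxel spacing
(0.357 × 0.357 × 0.5 mm), nested-ellipsoid brain phantoms with seeded
spherical lesions, and tri-ethnic cohort tables (120 per group) with the
published covariate distributions, configurable true effects and
missing-at-random gaps.

## Worked example

```bash
python examples/cohort_analysis_demo.py
```

simulates a cohort whose SA group carries a true diameter-on-age slope of
+11.3 μm/year with noise calibrated to the published confidence-interval
width, imputes the missing cells (m = 20) and refits the stratified model:

```
SA group, diameter ~ age (true +11.3 um/year), m = 20:
  estimate +11.31 um/year, 95% CI [3.73; 18.90], p = 0.0038, Cohen's D = 0.58
```

The estimate recovers the planted slope, and the CI width matches the
calibration target. `examples/vessel_geometry_demo.py` does the same for
geometry — a helical vessel of closed-form length 51.251 mm is measured at
51.158 mm (−0.18%) with a median fitted diameter of 2.923 mm against a true
3.0 mm — and `examples/lesion_mapping_demo.py` recovers two seeded 0.113 mL
lesions (0.117 / 0.123 mL) in their correct lobe × layer cells.

A thin CLI wraps the same functions for file-based runs
(`bametrics simulate-phantom | extract-geometry | lesion-load |
cohort-analyze`); every run writes a manifest (inputs with checksums,
parameters, seed) sufficient to reproduce it.

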