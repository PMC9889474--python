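# Methods

`deltarad` re-implements, as a tested pipeline, a time-serial CT
delta-radiomics analysis for progression-free survival (PFS) under
EGFR-TKI therapy: intra- and peritumoral features at two timepoints, their
per-day change, reliability filtering, survival-forest signatures, and
survival-based risk stratification.  Because no patient data ship with the
package, a synthetic cohort generator provides the study conditions; every
downstream stage is exercised and tested against that generator and
against analytic or brute-force oracles.

## Image geometry

Volumes are 3D scalar arrays indexed `(x, y, z)` with voxel-center world
coordinates `origin + index * spacing` (mm); NIfTI-1 is the on-disk
format.  All feature extraction runs on a 1 mm isotropic grid (linear
interpolation for intensities, nearest-neighbour with re-binarization for
masks), the standard harmonization step for multi-scanner CT.

Mask dilation is physical: a voxel joins the dilation of radius *r* when
its Euclidean distance to the mask is at most *r*, computed with the
exact Euclidean distance transform of the complement (spacing-aware, so
"5 mm" means 5 mm at any voxel size).  Two numerical choices matter:

* **Digitization offset.**  A segmented region is a union of voxel cubes
  whose surface lies beyond the outermost voxel *centers*; thresholding
  center-to-center distances at *r* therefore under-dilates systematically
  (≈6% volume error for a 10 mm ball dilated by 5 mm).  The threshold
  includes a `+0.25 * spacing` offset — the mean gap between a surface
  and the nearest center plane lies between 0 (center convention) and
  half a voxel (face convention) — which brings dilated volumes within
  ~2% of the analytic ball volumes across radii 6–15 mm.
* **Euclidean-then-clip.**  Peritumoral rings are built as
  `peri5 = (dilate(T, 5) \ T) ∩ L` and
  `peri10 = (dilate(T, 10) \ dilate(T, 5)) ∩ L` for tumor `T` and lung
  mask `L`.  Dilation is Euclidean in the full volume and *then* clipped
  to lung, rather than geodesic within lung; with ring widths of 5 mm the
  two differ only in rare concave-lung configurations.

The three regions are pairwise disjoint by construction and, intersected
with lung, partition the 10 mm dilation — both are asserted per patient
in the tests.

## Feature catalogue

A compact, fully specified catalogue replaces the proprietary
1691-feature bank of the original workstation software (whose
discretization, interpolators and filter bank are unpublished): 16
first-order, 12 shape, 6 GLCM and 6 GLRLM features.  Per scan that is 28
features × 3 regions + 12 tumor-shape features = 96.  The pipeline's
statistics are catalogue-agnostic; absolute feature counts are not
reproduction targets.

* Discretization: fixed bin *number* (default 32) over the in-region
  intensity range.  Synthetic intensities are HU-like but uncalibrated,
  so fixed bin width would be arbitrary; the choice is exposed in config.
  Texture features are consequently invariant to affine intensity shifts.
* Texture matrices are accumulated over the 13 unique 3D unit offsets at
  distance 1, restricted to voxel pairs (GLCM, symmetrized) or runs
  (GLRLM) lying inside the mask; feature values are averaged across
  offsets (not matrix-merged), making them invariant to translation and
  axis permutation.  Both extractors are tested against brute-force
  enumeration oracles on hundreds of random regions.
* Shape features use the tumor mask only — the rings are shells whose
  geometry is determined by the tumor contour, and shell meshes are
  degenerate.  Surface area and mesh volume come from a marching-cubes
  isosurface of the mask indicator *smoothed with a Gaussian of σ = 0.8
  voxels*: on raw binary masks the staircase facets inflate surface area
  by ~10% (digital-ball sphericity 0.91 instead of ≈1); with smoothing
  the ball's sphericity is 0.99.  Axis lengths are `4·sqrt(λ)` of the
  voxel-coordinate covariance eigenvalues, exact for solid ellipsoids.
* Degenerate inputs are flagged missing (NaN), never fatal: skewness and
  kurtosis of constant regions, GLCM correlation with a single occupied
  level, mesh features of planar masks.

## Reliability filtering and per-day deltas

Test–retest reliability uses the two-way mixed-effects, absolute-
agreement, single-rater ICC — ICC(A,1) in the McGraw–Wong taxonomy —
computed from the mean-squares decomposition and cross-checked against
`pingouin` in the tests.  The source only names "the ICC"; absolute
agreement is the stricter and more common radiomics choice, and the form
is stated in every report.  Features with ICC > 0.80 on the re-test
segmentations (30 patients by default) are retained; the decision is made
once per feature name and applied to baseline, follow-up and delta
versions alike.  Zero-variance features return ICC 1.0 by convention
(identical constant measurements) with a log line.

The delta of feature *f* over an inter-scan interval of `Δt` days is the
percentage variation per unit time

    δf = (f_F1 − f_F0) / (f_F0 · Δt)   [per day],

which removes the dependence on each patient's follow-up timing.  When
`|f_F0|` is below `1e-8 ×` the feature's training-cohort median absolute
value the ratio is meaningless and the delta is recorded missing rather
than ±∞.  Delta columns with more than 20% missingness are dropped;
remaining missing values are imputed with training-cohort medians.  The
ε guards, the column-drop decisions and the imputation medians are all
fitted on the training cohort and applied unchanged to validation — no
information flows back from validation data.

## Signature construction

Random survival forests (log-rank splitting, √p candidate features per
split, bootstrap per tree) provide the risk model; the risk score is the
ensemble mortality (sum of the ensemble cumulative hazard over the event
times).  Defaults: 500 trees for fitted signatures, 100 trees for the
forests inside the selection loop, minimum leaf size 6 (the backend
bounds leaf *samples*, not leaf events; with ~80% events this keeps ≥3
expected events per leaf).  Out-of-bag (OOB) predictions are reconstructed
per tree from the bootstrap RNG state, giving honest training-cohort risk
estimates.

Feature relevance is decided by the Boruta scheme: each iteration appends
a shadow (row-permuted) copy of every active candidate, fits a forest on
the joint table, and scores a "hit" for candidates whose importance
exceeds the best shadow's; two-sided binomial tests (p = 0.5) with
Bonferroni correction over the candidate set confirm or reject features,
rejected features leave the table, and leftovers are resolved by
comparing their median importance to the median best-shadow importance.

Two importance definitions coexist, deliberately:

* `permutation_importance` — the drop in *ensemble* OOB concordance when
  a feature column is permuted.  This is the cleanest single-feature
  relevance measure and is what the package reports for a fitted model.
* `tree_permutation_importance` — the Breiman-style *per-tree* OOB
  concordance drop, summed over the trees that split on the feature.
  This is what Boruta uses internally.  The reason is correlation: a
  radiomics table contains groups of near-collinear features (volume,
  surface area, axis lengths...), and at the ensemble level permuting one
  member changes almost nothing because its correlates carry the signal —
  on the default cohort ensemble-level Boruta confirms essentially no
  features, while the per-tree variant cleanly separates dozens of real
  features from the best shadow (an individual tree often lacks the
  correlates that mask the permuted feature).

Three signature pools mirror the comparisons of interest: `all` (F0 + F1
+ delta, all regions), `baseline` (F0 only) and `intratumor` (tumor
region only).  For each pool the confirmed features are ranked by median
importance over the Boruta iterations (ties broken lexicographically),
topped up from the tentative set if fewer than k = 10 confirmed; a pool
in which nothing is decidable (expected for weak pools) falls back to the
nominal top-10 with a warning so the comparison arm still exists.  The
final forest is refit on the selected features and its ensemble mortality
is min–max scaled to [0, 100] on the training cohort; scaling parameters
persist, and out-of-range validation scores are clamped with a warning.

## Clinical models and comparison

Univariate Cox fits (Efron ties, Wald CIs) screen the clinical
covariates: sex, age group (<60 / ≥60), smoking, ethnicity, T/N/M stage,
TKI drug, baseline tumor volume.  Categorical covariates expand against
the first (sorted) level as reference.  The clinical model is built by
classic greedy forward selection on the partial-likelihood AIC
(`2k − 2ℓ`): starting from the null model, add the covariate block with
the largest AIC decrease, stop when none lowers AIC; exact ties prefer
fewer parameters.  Note that plain AIC admits a noise covariate whenever
its likelihood-ratio statistic exceeds 2, which happens for the best of
several candidates in roughly half of null datasets — the selected model
is therefore *small*, not always empty, under the null.  The combined
model is a Cox fit on [signature score + selected clinical covariates].

Harrell's C counts a patient pair as comparable when the shorter observed
time is an event (tied times are not comparable) and credits tied risk
predictions 0.5.  Confidence intervals are percentile bootstrap over
patients (1000 draws), computed via quadratic forms of resample
multiplicity vectors over precomputed pair matrices — algebraically
identical to re-enumerating pairs, at a fraction of the cost.  Models are
compared with a paired patient-level bootstrap of ΔC = C₁ − C₂ (2000
draws), `p = 2·min(P(ΔC* ≤ 0), P(ΔC* ≥ 0))` with the (B+1)-denominator
small-sample correction; identical predictions return p = 1 by
convention.  The source names only "a pairwise nonparametric test"; the
paired bootstrap was chosen for distribution-free validity with paired
predictions (a jackknife variance test is the documented alternative).

## Stratification and prognostic accuracy

The signature cutoff maximizes the two-sample log-rank statistic over
every observed training score within the [0.10, 0.90] quantile window
(maximally selected log-rank statistic); ties break toward the median
score, and the full cutoff-vs-statistic profile is kept for plotting.
The quantile window avoids degenerate small groups.  Because the cutoff
maximizes the statistic, the plain log-rank p on the resulting split is
anti-conservative; the report says so explicitly and additionally carries
a permutation-adjusted p (scores permuted 200 times, cutoff re-searched,
maximum statistic compared).  The cutoff is fitted on training only and
applied unchanged to validation; an empty validation group suppresses
group-level statistics with a warning.

Kaplan–Meier curves use the product-limit estimator; the median is the
first time S(t) ≤ 0.5 (right-continuous convention), undefined when never
reached.  Prognostic accuracy at 6, 9 and 12 months uses the
cumulative-cases / dynamic-controls time-dependent ROC with inverse-
probability-of-censoring weights from the Kaplan–Meier censoring
estimator (the incident-case variant is a documented alternative; the
cumulative definition matches "progressed by month t").  Months and days
convert through one constant (30.44 days/month).

## Synthetic cohort generator

Each patient is an ellipsoidal lesion (equivalent radius 6–16 mm,
anisotropy ±20%) rendered at 1 mm isotropic spacing on an HU-like
background: lung parenchyma at −800 HU, lesion core ≈ 40 ± 15 HU, an
intratumoral Gaussian-random-field texture (correlation length 2–5 mm,
amplitude 30–80 HU), a peritumoral rim whose intensity decays
exponentially at 0.2–0.5 mm⁻¹, per-scan acquisition noise of 20 HU, and
— near 30% of lesions — a high-intensity chest-wall slab excluded from
the lung mask, exercising ring clipping.  The texture field is shared
between the two timepoints (same lesion), acquisition noise is not.

Three per-day rates evolve the lesion linearly over the inter-scan
interval (log-normal, median 35 days, truncated to [16, 128]): volume
(mean −0.002/day, SD 0.004 — lesions shrink on average under therapy),
texture amplitude (SD 0.004) and rim decay (SD 0.004), all floored so a
regressing lesion never vanishes.  The latent risk is the fixed linear
combination `110·v + 150·τ + 210·ρ` of the three rates, and PFS follows
an exponential proportional-hazards law (scale 16 months at zero risk)
with uniform censoring over 193.5 months.  The last two constants were
calibrated once, by Monte Carlo on the latent model, to an 83% event
fraction and ≈11-month median PFS.

Baseline texture amplitude shifts the volume- and peri-rate means by 1.1
and 0.5 rate-SDs per unit of its standardized value: more heterogeneous
tumors progress faster.  This gives baseline appearance a moderate,
indirect prognostic value — the regime in which single-timepoint
signatures work but time-serial ones work better.  The resulting
population-level concordances of the four information sets are ≈0.76
(all rates) / 0.68 (intratumoral rates) / 0.61 (baseline appearance) /
0.50 (clinical covariates, independent of risk by default; a config
switch adds a weak baseline-volume effect).  Re-test masks jitter the
segmentation boundary by ≤1 mm in smooth patches (signed distance to the
mask surface thresholded at a clipped random field), holding Dice ≥ 0.90.

What the generator does *not* emulate: CT physics (beam hardening, dose,
reconstruction kernels), scanner-to-scanner effects, respiratory motion,
irregular or cavitating lesion morphology, and real biological coupling
between texture and outcome.  Passing tests therefore demonstrate that
the pipeline recovers a planted dynamic signal under realistic geometry,
noise and censoring — not that the signature generalizes to clinical CT.

## Problem sizes and determinism

Default cohorts are 131 training / 41 validation patients, the sizes the
emulated study design calls for; heavier statistical checks (type-I
error, Boruta recovery, null forests) run at n = 200–500 with hundreds
of replicates.  Every stage draws its seed deterministically from the
master seed and the stage name (`SeedSequence(master, crc32(stage))`),
so a full run is byte-reproducible and any stage can be re-run in
isolation; the run manifest records the config hash, stage seeds and
output checksums.

## Known limitations

* The catalogue omits filtered-image (wavelet/LoG) features and the
  GLSZM/NGTDM families, and is not IBSI-certified.
* Validation cohorts of ~41 patients give C-index CIs of ±0.1; adjacent
  models in the hierarchy can swap on unlucky draws, as in the emulated
  study where several validation comparisons did not reach significance.
* The clinical forward-AIC model can include chance covariates under the
  null (see above); this mirrors the behaviour of plain AIC selection.
* Proportional-hazards diagnostics, competing risks, calibration curves
  and decision-curve analysis are out of scope.
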