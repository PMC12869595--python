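# Methods

This note documents the models, defaults and numerical choices behind
`tractvar`, and what the synthetic cohorts do and do not establish.

## Study structure

Subjects are binned into eight lifespan epochs (0–2, 2–5, 5–12, 12–21,
21–35, 35–55, 55–75, 75+ years). Each epoch belongs to exactly one
acquisition cohort (Infant, Development, YoungAdult, Aging); because
scanner and protocol differences bias quantitative features, epoch-pair
comparisons are restricted to pairs within one cohort: infancy
(0–2 vs 2–5), development (5–12 vs 12–21), middle adulthood (35–55 vs
55–75) and late adulthood (55–75 vs 75+). The default registry lists 64
bundles (TractSeg nomenclature) in six categories, with 28 left/right
homologue pairs and 8 midline bundles; the list is a YAML data file and
fully user-replaceable — every analysis depends only on the count,
category and pairing structure, not on specific bundle identities.

## Spatial measures

Displacement fields are subject→template 3-vectors in mm stored on the
template grid. Analyses assume an isotropic voxel size and work in voxel
index space scaled by that size; no world affine beyond this is handled
(a deliberate simplification for template-space analysis). The
log-Jacobian uses central differences in the interior and one-sided
differences at the boundary, in physical coordinates; voxels with a
non-positive determinant (folding) are recorded as NaN and counted in a
log message rather than aborting the run.

The normalised population overlap at threshold t counts voxels with
population frequency ≥ t (not strictly greater): a core carried by 100%
of subjects must count at the 90% level, and the all-identical-masks case
then yields exactly 1.0 at every threshold. The normalising mean volume
is the cohort mean of per-subject mask volumes computed in template
space, supplied by the caller, keeping numerator and denominator in the
same space.

## Statistical tests

* **Wilcoxon signed-rank** (hemispheric asymmetry): zero differences are
  dropped; |differences| are ranked with average ranks for ties. With at
  most 25 non-zero pairs the two-sided p-value is exact — a dynamic
  program over doubled ranks enumerates the 2^n equally likely sign
  assignments — and the two-sided p is min(1, 2·min(P(W⁺≤w), P(W⁺≥w))).
  Above 25 pairs a normal approximation with continuity correction and
  the standard tie correction to the variance is used. All pairs tied
  yields statistic 0, p = 1 (no evidence, not an error).
* **Two-sample t** (epoch mean change): pooled-variance Student t by
  default (Welch by flag). Two zero-variance samples give p = 1 when the
  means agree and a flagged degenerate p = 0 otherwise.
* **Two-sample F** (epoch variance change, hemispheric variance
  asymmetry): F = s²_a/s²_b with n−1 denominators, two-sided
  p = min(1, 2·min(P(F≤f), P(F≥f))).
* **BH-FDR**: step-up adjusted p-values
  p̃_(i) = min_{j≥i} m·p_(j)/j clipped at 1; rejection at p̃ ≤ q, which is
  exactly the classic rule p_(i) ≤ i·q/m (the ≤ matters: five equally
  spaced p-values 0.01…0.05 at q = 0.05 are all rejected). Families are
  per (feature, analysis, epoch-pair) — 64 (or 28 bilateral) tests per
  family — not one global correction.
* Sample variances use n−1 throughout.

Variance asymmetry is tested with a two-sample F per homologue pair. The
choice of statistic for variance asymmetry was genuinely open (a paired
test on what units is ambiguous for variances); the F-test is the
standard two-population equal-variance test and composes with the same
FDR machinery.

## Brain–behaviour model

Features and behaviour scores are z-scored within each dataset
(Development, YoungAdult, Aging — infants carry no behaviour battery and
are excluded by a hard filter), per (dataset, column). Values more than
k = 4 SD from their (dataset, column) mean are removed; removal is per
cell (the subject's other measurements survive), and re-running without
re-standardising is a fixed point. Values are not re-standardised after
removal.

Each grid cell fits OLS:
Behaviour ~ β0 + β1·Feature + β2·Dataset + β3·Feature×Dataset + β4·Age + β5·Sex + ε
with treatment coding against the Development reference (the first
lifespan stage in the analysis set), age in raw years centred within
dataset, and sex as a 0/1 indicator. β1 is therefore the Development
slope; per-dataset simple slopes are β1 plus the matching interaction
dummy. The interaction is judged by a joint partial F-test on both
Feature×Dataset dummies (one decision per cell), computed from the
nested-model residual sums of squares. A rank-deficient design raises an
error naming the most collinear column pair. The scan's OLS core is a
compact numpy routine (lstsq, classical standard errors, nested-RSS F)
for throughput across the 576-cell grid; the test suite verifies it
coefficient-for-coefficient against statsmodels and the partial F against
an explicit two-fit oracle.

Significance is Bonferroni at α/(pathways × features) = 0.05/576 per
behavioural measure, matching the grid size per behaviour rather than a
global correction across all eight behaviours.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume,
with every planted effect recorded in a `GroundTruth` object.

* **Cohort**: n per epoch (default 25), ages uniform within epoch bounds
  (last epoch capped at 100 y), sexes balanced.
* **Masks**: each bundle is a deterministic spherical core (radius =
  0.095 × grid extent ≈ 6.1 mm on the default 32³ grid of 2 mm voxels)
  plus a stochastic periphery in which voxel v enters independently with
  p(v) = exp(−d(v)/λ), d the distance from the core surface and
  λ = 3.5 mm. These two constants were fixed from the closed-form
  continuous field — V(p≥t)/V_mean with V(p≥t) ∝ (R + λ ln(1/t))³ and
  V_mean = (4π/3)R³ + 4π(R²λ + 2Rλ² + 2λ³) — so that the designed
  90%/50% superlevel volumes are ≈ 0.20 and ≈ 0.47 of the mean volume,
  the overlap regime reported for real populations. Right-hemisphere
  masks are the mid-sagittal mirror of their left homologue (same random
  draws), so homologue pairs have identical volumes by construction.
* **Displacement fields**: white noise smoothed with a periodic Gaussian
  filter (σ = 4 voxels), renormalised to unit variance by the discrete
  impulse-response norm, then scaled so that E‖u(x)‖ = base + gradient·r(x)
  (defaults 0.5 mm + 0.05 per mm of distance from the grid centre) times
  an epoch multiplier rising from 0.7 in early infancy to 1.25 in late
  life — the deep→superficial, infancy→ageing gradient. The magnitudes
  are qualitative: no quantitative per-depth displacement norms exist to
  match.
* **Features**: value = trajectory(age) + leftward offset + noise.
  Trajectories are two-piece curves (exponential rise to a peak, linear
  decline) per feature; FA/ICVF rise and decline late, diffusivities
  fall early and creep back up. Noise SD = feature SD × epoch multiplier;
  the default profile (1.50, 1.15, 1.15, 0.95, 0.90, 0.90, 1.10, 1.45)
  yields variance ratios ≈ 0.59, 0.68, 1.49, 1.74 across the four
  comparison pairs — convergence in early life, divergence in ageing.
  Default asymmetries: +0.02 FA (AF), +0.01 FA (SLF_III), +250 mm³
  volume (CST), and a 1.5× left variance excess for AF volume. The FA
  noise SD of 0.03 is a realistic between-subject SD for bundle-averaged
  FA. Volume is additionally scaled by a per-subject TBV factor
  (SD 6%) around a lifespan TBV curve; volume_norm is volume/TBV.
* **Behaviour**: eight scores; each is a sum of coefficient × cohort
  multiplier × within-cohort-z(feature) couplings plus small age and sex
  effects and unit-SD noise. Default couplings tie each behaviour to one
  (pathway, feature) with multipliers (1.0, 0.4, 0.3) for Development,
  YoungAdult, Aging — the development-strongest pattern.

Random streams are keyed by stable CRC-32 hashes of bundle (and subject,
where applicable) names under a single seed: adding a bundle never
perturbs the draws of existing bundles, and within a bundle subjects
draw in order, so prepending subjects would, but appending does not,
change earlier draws. Identical config + seed reproduces outputs
bit-exactly.

What the synthetic cohorts do **not** emulate: spatial correlation of
periphery voxels (real peripheries are contiguous, not independent per
voxel), registration error, scanner/site effects beyond a cohort label,
non-Gaussian feature noise, missing data patterns, and correlated noise
across features or pathways (apart from volume/volume_norm sharing their
noise and all features sharing the age trajectory). Calibration and
power results transfer to real data only to the extent these assumptions
hold; the suite demonstrates the machinery is correct and calibrated
under its stated model, not that real effect sizes match.

## Calibration and recovery checks

Under full-null configurations (no offsets, flat trajectories and
variance profile, zero couplings) each scan's global-null any-rejection
rate is compared to its nominal level over repeated simulations: for a
BH-controlled scan this rate equals q exactly when p-values are
independent and continuous, and for the Bonferroni behaviour grid it is
bounded by α. Simulation sizes — 500 replicates at ~100–240 subjects for
the asymmetry, lifespan and variance scans, 200 replicates of the full
576-cell grid for the behaviour scan, and 25–60 replicates for the power
and coverage checks at 200 paired subjects / 300 subjects per cohort —
were chosen as the smallest sizes at which the binomial confidence bands
are meaningfully narrow.

## Known limitations

* No continuous age modelling (splines/GAMs); epochs are compared
  discretely, as designed.
* No mixed effects or site harmonisation; the dataset dummy is the only
  protocol adjustment in the behaviour model.
* The overlap index is grid-resolution dependent; values are only
  comparable between maps on the same grid.
* Discrete Wilcoxon p-values make BH slightly conservative at small n;
  calibration simulations use ≥100 pairs where the effect is negligible.
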