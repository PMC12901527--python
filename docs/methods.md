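# Methods

This note documents the models, conventions and numerical choices behind
`vatslice`, and what the synthetic study does and does not establish about
real data.

## Coordinate and grid conventions

Axial position is measured in mm from the most caudal acquired slice,
increasing caudal → cranial; slice *i* (0-based) is centred at
`(i + 0.5) · dz` with `dz = 3 mm` by default.  The anatomical grid has 40
ordered locations: 26 equidistant points spanning femoral heads (FH) to the
L5 center — per individual, `linspace(FH, L5, 26)`, so the physical step is
`distance/25` — followed by the 14 disc/vertebral centers `L5/4 … Th10`.
Caudal labels use the cohort-level step of 0.5 cm (the population mean
FH–L5 distance of 12.9 cm divided by 25 is 0.516 cm, 0.5 cm at one-decimal
rounding); the per-individual positions underneath those labels vary with
the individual's femoral-head distance.

Standardization reads vertebral/disc locations from the **nearest axial
slice** (no sub-slice interpolation: at 3 mm partitions the quantization is
below other error sources) and caudal points by **linear interpolation** of
the per-slice amounts.  Interpolating pixel counts or areas is equivalent —
they differ by the constant in-plane voxel area, and all grid values are
normalized to percent of total VAT per slice.  Percentages are normalized
over the covered trunk (femoral heads to cardiac apex) only.

Two consequences worth stating explicitly:

* **Scale invariance** — multiplying all slice areas by a constant leaves
  the standardized profile unchanged.
* **Height independence holds for locations, and for values up to a level
  factor.**  The grid aligns anatomical positions across statures, but a
  longer trunk spreads 100% of VAT over more slices, which uniformly lowers
  every per-slice percentage.  Two participants with the same
  landmark-anchored shape and different vertebral spacing therefore produce
  standardized profiles that are identical up to one multiplicative
  constant (tested to 0.1% on the caudal segment).  Exact pointwise
  equality is not attainable for a per-slice share.

## Synthetic cohort

### Covariates

Participants are drawn from a calibration table holding per sex × BMI group
counts and moments (age, height, BMI, total VAT).  The default table
reproduces the published population of 11,036 participants (5,681 men).
Within a group: BMI is truncated-normal on the group interval; height is
normal (truncated at ±4 sd); weight is derived from BMI and height so the
BMI consistency invariant holds exactly; age is drawn uniformly within
10-year bins whose weights are the normal(mean, sd) mass on each bin —
the source table gives only means ± sd, so bin means are matched
approximately; total VAT is log-normal with group mean and sd matched
(VAT is positive and right-skewed).  Within strata the covariates are
drawn independently — the joint age × BMI × VAT covariance is not published
and the independence assumption is a modeling choice.

### Spine geometry

Vertebral center-to-center gaps (L5→L4 … Th11→Th10: 3.9, 3.8, 3.7, 3.6,
3.4, 3.2, 3.0 cm at a 171.7 cm reference height) scale linearly with body
height and receive 3% log-normal jitter; disc centers sit midway.  The
L5-to-femoral-head distance is Normal(12.9, 1.1) cm truncated to 9–17 cm
(truncation avoids non-physical geometries; at ±3.5 sd it shifts the mean
by < 0.001 cm).  Coverage runs from just below the femoral heads (15 mm) to
40 mm above Th10 (cardiac apex).

### Craniocaudal VAT density

The noise-free density is a two-component mixture anchored to landmarks:

* a **pelvic dome**: Gaussian centred midway between FH and the
  pelvic/abdominal boundary (3 cm below L5), width (boundary − FH)/3.2;
* an **abdominal component**: two-sided Gaussian centred at a vertebral
  landmark (L3 in men; L5/4 shifting to L3 with BMI in women), σ = 4 cm on
  the caudal side and 8 cm on the cranial side.  The heavier cranial
  shoulder keeps a realistic share of VAT up to Th10 rather than letting
  the profile collapse to zero above the peak.

Only the ratio of the two component weights matters — profiles are
normalized per individual, and slice areas are scaled so that
Σ area × thickness equals the participant's drawn VAT volume exactly.
Default weights make the pelvic level decrease and the abdominal peak
increase with BMI, with a generally higher pelvic level in women; the
age-averaged male profile peaks at L3 in every BMI group.

### Age effect and the planted crossing

Age enters multiplicatively: `f_age(z) = f0(z) · (1 + δ · r(z))`, with δ
the age in decades relative to 45 years and `r` a **hinge**: zero on one
side of a pivot, linear on the other (sign such that older individuals
carry relatively more abdominal and less pelvic VAT).  Because standardized
profiles are normalized per individual, curves for different ages cross
exactly where the local relative tilt equals its density-weighted mean;
a hinge crosses its own mean level once, so the crossing is unique, and the
pivot is solved per individual (bracketed scan + Brent root-finding on the
exact readout functional — nearest slice or linear interpolation, matching
the standardization) so that the crossing sits exactly on the planted grid
label.  The hinge slope is scaled so the density-weighted mean absolute
relative contrast is |age_slope_pelvic| (default 0.08) per decade, bounded
so the density stays positive over ages 20–73; pivots near a trunk end get
correspondingly steeper slopes, otherwise tail plantings would carry almost
no age contrast in the bulk of the profile.

A structural point discovered while designing this: a tilt that merely
rescales the two component amplitudes with age **cannot** place the
crossing — after normalization such curves can only cross where the local
pelvic/abdominal mix equals the global mix, a location fixed by the
component shapes alone.  Planting an arbitrary crossing requires a tilt
with a positional degree of freedom; the hinge is the simplest monotone
choice.

Default planted locations follow the reference locations reported for the
real cohort (men: L5/4, L5−1 cm, L5−2.5 cm, L2/1, L5−7 cm for BMI groups
I–V; women: L5, L5−2.5 cm, L1, L2/1, L1), so the qualitative caudal shift
with BMI in men and the cranial locations for women with obesity are built
into the default study.

### Noise

Two independent knobs, both zero in "noise-free" runs:

* `noise_sd` (default 0.0025 fraction/cm): additive Gaussian per-slice
  density noise, clipped at zero — measurement/segmentation noise.
* `shape_jitter` (default 0.25): log-normal relative jitter of the two
  component weights per individual — biological profile variability.  This
  is the dominant source of estimation error; at the default it yields
  per-group Pearson correlations between single-slice estimates and
  reference volumes of roughly 0.6–0.97 across strata, bracketing the
  0.72–0.89 range reported for real data.

Jitter is applied before the pivot solve, so the planted crossing remains
exact per individual; noise only adds variance, not bias, to the stratum
means.

### Voxelization

Masks place one filled ellipse (axis ratio 1.5) per slice, choosing the k
voxels closest in elliptical radius with k = round(area / voxel area), so
the rendered area matches the request within half a voxel (0.0098 cm² at
1.4 × 1.4 mm) per slice; per-slice area is the only quantity downstream
stages consume, so no organ-level realism is attempted.  Requests exceeding
a 500 mm field of view are rejected.  Spine labels are 3 × 3 × 1 blobs at
the landmark positions; centroid localization recovers them within half a
slice.

### Planted exclusions

`inject_exclusions` sets the requested numbers of fat–water-swap, corrupted
and missing-anthropometry flags on disjoint participants, forces the
requested number underweight, and moves participants into otherwise-empty
strata in batches of at most 9 to plant small-stratum exclusions.  So that
downstream counts match the request exactly, naturally small strata are
first repaired by reassigning their members' ages (and, if a whole
sex × BMI group is too sparse, their BMI group) into the largest receiving
stratum of the same sex.  The repair slightly distorts the stratum
marginals and exists purely so the exclusion cascade can be exercised with
exact expected counts.

## Cohort analysis

* **Exclusion order**: fat–water swap → corrupted → missing anthropometry →
  underweight (BMI < 18.5) → strata with n < 10.  Counts are reported per
  criterion and total removals are conserved.
* **Age 60** belongs to the oldest group (the printed group boundaries
  leave 60 formally unassigned); ages above 70 are subsumed into it.
* **Spread metric**: the range (max − min) of age-group means per location;
  variance is available behind a switch.  The search is restricted to
  locations whose pooled mean percentage is at least 10% of the profile
  maximum: a near-empty slice trivially has zero age spread but carries no
  signal for volume estimation (whether the original analysis restricted
  its search space is not stated; without the restriction the argmin lands
  in the coverage tails).  Ties break toward the largest pooled mean.
* **Factor**: ratio of group means, f = 1000 · mean(V)/mean(A), pooled over
  age groups — the group-level reading of "reciprocal of single-slice VAT
  percentage"; the mean of per-participant ratios is available behind a
  switch for sensitivity checks.  On the cohort that produced it, the
  ratio-of-means factor makes the group mean signed error exactly zero.
* **t-test**: pooled-variance two-sample statistic with df = n₁ + n₂ − 2;
  zero pooled variance returns t = 0.  **KDE**: Gaussian kernel, Silverman
  bandwidth; constant input is rejected (zero bandwidth).
* Significance threshold for reported tests: α = 0.01.

## Estimation and validation

`estimate_vat` is the exact linear formula (homogeneous of degree 1 in
area).  Correlation validation reports Pearson r and ordinary least squares
in both orientations (the regression orientation is not standardized in the
field; both slopes are written out).  Error metrics report mean signed
error ± sd in liters; the **relative mean absolute error** is implemented
as |mean signed error| / mean reference × 100 — this definition reproduces
the published population-level values from their printed inputs
(0.07/4.8 → 1.46% vs printed 1.44%; 0.06/2.5 → 2.40% vs 2.37%), whereas
mean(|error|)/mean(V) would be an order of magnitude larger given the
printed error sd; the alternative remains available behind a switch, and no
claim is made that the reproducing definition is the original authors'
intent.  Boxplot statistics use the 1.5 × IQR whisker convention.

## Problem sizes and tolerances

* Planted-location recovery is exercised noise-free at 1,000 participants
  per age group (where recovery is exact in every stratum) and with default
  noise at 2,000 per sex × BMI stratum (recovery within one grid step);
  below a few hundred participants per age group the location estimate is
  noise-limited, mirroring the n ≥ 10 stratum-size exclusion of the
  original design.
* Factor recovery is checked against an independently coded readout of the
  generator's ground-truth areas (2% tolerance; observed agreement ~1e-3).
* The estimator-exactness check runs on a geometry-homogeneous noise-free
  stratum (equal heights, fixed femoral-head distance, no spacing jitter)
  so that the only error source is voxel quantization; observed
  per-participant errors are ≪ 1%, tested against a 2% bound with r > 0.99.
* The caudal-interpolation oracle (dense 0.1 mm resampling) agrees to 1e-9
  relative; per-slice fraction normalization holds to 1e-9.

## What the synthetic study does not show

The generator plants the structure the pipeline is designed to find: smooth
two-component profiles, a unique age crossing per stratum, independent
covariates within strata, and elliptical single-region masks.  Passing
tests therefore demonstrate correctness of the bookkeeping, standardization,
search and estimation machinery — not that real VAT profiles have a unique
age-independent location, nor the accuracy of any particular published
factor.  Real segmentations contribute errors (partial fat–water swaps,
segmentation boundaries, multi-region VAT topology) that have no synthetic
counterpart here beyond a per-slice noise term and an exclusion flag.

## Known limitations

* Per-slice percentages scale inversely with trunk length; comparisons of
  absolute levels across very different statures retain that factor.
* The intersection search needs at least two age groups per sex × BMI
  stratum and a level floor (10% of peak by default); strata that fail
  either are skipped with a warning rather than given a factor.
* The small-stratum repair in `inject_exclusions` mildly reshapes age
  distributions; it is intended for exclusion bookkeeping studies, not for
  inference on age structure.
* `age_slope_abdominal`, when set explicitly, switches to an
  amplitude-only tilt whose crossing is emergent (shape-determined) rather
  than planted.
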