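# vatslice

Craniocaudal visceral adipose tissue (VAT) profiles and age-independent
single-slice volume estimation from MRI segmentations.

## The problem

Whole-trunk MRI with automated fat segmentation is the reference method for
quantifying visceral adipose tissue, but many studies and most clinical
protocols measure a **single axial slice** and scale its VAT area to a
volume.  How well that works depends on *where* the slice is taken: the
craniocaudal distribution of VAT differs between men and women, shifts with
BMI, and — critically — changes with age, so a slice location chosen for one
age group is biased in another.

`vatslice` implements the analysis pipeline for choosing **age-independent
reference locations** per sex and BMI group and estimating total VAT volume
from them:

1. **Profile extraction** — per-slice VAT cross-sectional areas from a
   binary mask volume are expressed as percentage of total VAT per slice and
   standardized to a 40-point anatomical grid: 26 equidistant points from
   the femoral-head level (FH) to the center of L5 (labelled `L5-0.5 cm` …
   `L5-12.5 cm` at the cohort step of 0.5 cm), then the vertebral-body and
   intervertebral-disc centers `L5/4` … `Th10`.  Indexing by anatomical
   label removes the direct influence of body height.
2. **Cohort analysis** — exclusion cascade (imaging artifacts, missing
   anthropometry, underweight, strata with n < 10), stratification into
   five BMI groups (boundaries 18.5/25/30/35/40 kg/m²) and five 10-year age
   groups, per-stratum mean profiles ± SEM, and the **intersection search**:
   the grid location where the age-group mean profiles of a sex × BMI
   stratum differ least.
3. **Estimation** — the scaling factor *f* for each sex × BMI group is the
   reciprocal of the mean single-slice VAT fraction at the reference
   location, and total VAT is estimated as

   ```
   V̂ [l] = A [cm²] × f / 1000,      f = 1000 × mean(V) / mean(A)
   ```

   equivalently *f* = slice thickness [cm] / mean per-slice VAT fraction.
   Validation reports Pearson r, regression lines, signed errors and
   relative mean absolute errors per group.
4. **Synthetic cohort** — because population imaging data of this kind are
   access-restricted, the package ships a calibrated generator producing
   participant covariates matched to the published cohort moments, spine
   geometries (L5–FH distance ~ Normal(12.9, 1.1) cm), two-component
   craniocaudal VAT density profiles with a *plantable* age-independent
   crossing, and voxelized VAT/spine NIfTI volumes (3 mm partitions,
   1.4 × 1.4 mm in-plane).  Every downstream stage is testable offline
   against planted ground truth.

## Worked example

Run the full synthetic pipeline from the command line (about 15 s):

```bash
cat > demo.yaml <<EOF
seed: 7
n_participants: 2000
outdir: demo
EOF
vatslice --config demo.yaml simulate
vatslice --config demo.yaml extract
vatslice --config demo.yaml analyze
vatslice --config demo.yaml estimate
```

`analyze` writes the factor table (`factor_table.csv` / `.json`).  With
seed 7 and the default study conditions it contains, among others:

```
sex,bmi_group,location,factor
M,I,L5/4,63.55883167763513
M,II,L5-1 cm,155.89605917729293
F,I,L5,23.876483222694123
F,II,L5-2.5 cm,46.42768705472262
```

Each row says: for that sex × BMI group, measure the VAT area on the single
axial slice at `location` and multiply by `factor`/1000 to estimate total
VAT in liters.  For men of BMI group I the selected location is the L5/4
disc — exactly the crossing the generator planted for that stratum; with
2,000 participants the larger strata recover their planted locations, while
sparse ones (e.g. group IV with ~40 participants) remain noise-limited.

`estimate` writes per-participant estimates and a validation summary
(`validation_summary.csv`); with seed 7 the men-I row reads

```
sex bmi_group   n  pearson_r  mean_error_l  sd_error_l
  M         I 303      0.823          -0.0       0.746
```

i.e. the single-slice estimate correlates with the reference volume at
r = 0.82 and is unbiased on the cohort that produced the factor (the
ratio-of-means factor makes the in-sample mean signed error vanish by
construction); the residual spread of ±0.75 l reflects the inter-individual
profile variability the generator plants.

The same operations are available as library functions
(`generate_participants`, `standardize_profile`, `find_intersection`,
`derive_factor`, `estimate_vat`, …); see the docstrings and
`docs/methods.md`.

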