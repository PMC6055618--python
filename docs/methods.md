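# Methods note

This document describes the statistical model and numerical choices behind
`vbasym`, a whole-brain voxel-based asymmetry (VBA) pipeline for studying
hemispheric language dominance (HLD), together with what the bundled synthetic
cohort generator does and does not emulate.

## 1. Model

### 1.1 Asymmetry index

For each voxel of the right hemisphere in a left–right symmetric template
space, let `r` be the subject's modulated grey-matter value at that voxel and
`l` the value at the homologous left-hemisphere voxel (obtained by warping the
left–right flipped image into the same space). The asymmetry index is

```
AI = (l - r) / (0.5 * (l + r))
```

AI is bounded in [-2, 2]; positive values mean more grey matter on the left.
Because each AI voxel already encodes both hemispheres, analysis is restricted
to a right-hemisphere mask (`x > 0` and template grey matter above a
threshold). Voxels where `0.5 * (l + r)` falls below a small epsilon
(`ai_eps_frac` times the template maximum, default 1e-6) are set to 0 rather
than divided; this only affects voxels with essentially no tissue.

### 1.2 Symmetric template and spatial normalization

A left–right symmetric grey-matter template is built iteratively:

1. Initialize with the symmetrized grand mean of all subjects' original and
   flipped images: `T0 = 0.5 * (M + flip(M))` where `M` is the pooled mean.
2. Each iteration registers every original and flipped image to the current
   template with a multiresolution demons-style algorithm, averages the
   Jacobian-modulated warped images, and re-symmetrizes the result.

The template's symmetry residual `max |T - flip(T)|` is forced to 0 by
construction and required to be ≤ 1e-6. One iteration
(`template_iterations = 1`) is the default; it is enough for the desk-scale
synthetic cohorts, where subjects differ from the template by small rigid
jitter and regional volume effects.

The grid uses a RAS-like, centred, diagonal affine. The x-dimension must be
odd so that the mid-sagittal plane `x = 0` lies exactly on a voxel column;
left–right flipping is then an exact voxel-column permutation
(`data[::-1, :, :]`) with no interpolation, which makes flip an exact
involution and the symmetrization bit-exact.

### 1.3 Registration

Registration is a greedy multiresolution demons variant:

- Force term `-diff * grad / (|grad|^2 + diff^2 * K)` with
  `K = 1 / mean_spacing^2` (the classical demons normalization).
- The update field is smoothed with a Gaussian (`reg_update_sigma_mm`,
  default 4 mm, "fluid" regularization) and the accumulated field with a
  stronger Gaussian (`reg_field_sigma_mm`, default 12 mm, "elastic"
  regularization).
- Each iteration uses step-halving so that (a) the sum of squared differences
  never increases and (b) the Jacobian determinant of `x + u(x)` stays
  strictly positive. This keeps the transform diffeomorphic in practice
  without implementing a full stationary-velocity-field exponential.
- Three resolution levels (factors 4, 2, 1) with 60/40/20 iterations.

The relatively strong field regularization (12 mm) was chosen because
intensity-driven demons otherwise concentrates displacement at structure
boundaries: with weaker smoothing, recovered volume changes overshoot (an
injected AI of 0.4 was recovered as ~0.54) and interior mass is not moved
coherently. With the default parameters a 6 mm rigid shift of a blob phantom
is recovered to ~0.1 mm and injected asymmetries of 0.4 are recovered within
15% relative error.

### 1.4 Jacobian modulation

Warped images are multiplied by `det(I + du/dx)`, computed with central
differences, so that total tissue volume is conserved ("modulation").
For interior structures (away from the grid boundary) mass is conserved to
well under 0.5%.

### 1.5 Smoothing

AI maps are smoothed with a mask-normalized Gaussian:
`smooth(AI * mask) / smooth(mask)`, re-zeroed outside the mask, with
`sigma = FWHM / 2.3548`. Default FWHM is 8 mm, standard for VBM-style
analyses. Mask normalization prevents the zero background from biasing AI
toward 0 at the mask edge; a constant AI field is an exact fixed point.

### 1.6 Voxel-wise inference

Per-voxel statistics come from a closed-form OLS GLM (cell-means coding for
groups, mean-centred covariates; `t = c'b / sqrt(sigma^2 c'(X'X)^-1 c)`).
Cluster-level inference uses the max-cluster-size permutation null:

- Cluster-forming threshold: voxel `p < 0.001` (Student t quantile).
- Connectivity: 26-neighbourhood (configurable 6/18/26) via
  `scipy.ndimage.label`.
- One-sample (within-group) tests permute by sign flips; group contrasts
  permute group labels (covariates stay attached to subjects).
- When the number of distinct permutations (2^n sign flips, or multiset label
  permutations) does not exceed the requested count, they are enumerated
  exhaustively.
- p-values use the add-one estimator `p = (1 + #{null >= observed}) / (1 + B)`,
  which is exact (never anti-conservative) for exchangeable nulls.
- A cluster is significant when `p_FWE <= 0.05` (default `fwe_alpha`).

Default `n_permutations` is 1000; a lower bound of 100 is enforced.

### 1.7 Cluster profiling and consistency

For significant clusters from the left-vs-right HLD contrast, the pipeline
reports per subject: mean **unsmoothed** AI over cluster voxels, and left- and
right-hemisphere grey-matter content (sum of the modulated warped flipped /
original image over cluster voxels times voxel volume, in mm^3). Smoothed AI
is used only to form clusters; profiling uses unsmoothed AI so the reported
effect sizes are not attenuated by the kernel.

Per-cluster z-scores are computed by pooling the two compared groups (mean 0,
SD 1 with `ddof=1`); a subject is "consistent" when the sign of its z-score
matches the sign of its group's mean z-score. Percentages are reported at one
decimal (half away from zero).

### 1.8 Cohort statistics

- Group counts and one-decimal percentages.
- 2x2 chi-square tests in closed form: Pearson
  `chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))` and the Yates variant with
  `|ad - bc|` replaced by `max(0, |ad - bc| - n/2)`. Both match
  `scipy.stats.chi2_contingency` to machine precision.
- One-way ANOVA on handedness scores with Bonferroni-adjusted pairwise
  t-tests, plus `anova_from_summary` to reconstruct an omnibus F from printed
  per-group means/SDs/ns (useful for cross-checking published tables; limited
  by the rounding of the printed summaries).

## 2. Synthetic cohort generator

### 2.1 What it emulates

- A symmetric "anatomy" built from mirrored ellipsoid structures (brain
  envelope plus insula-, hippocampus- and planum-temporale-like regions),
  max-composed and Gaussian-blurred, then symmetrized bit-exactly.
- Group-specific hemispheric asymmetry: a multiplicative injection scales the
  left copy of a structure by `(2 + delta)/2` and the right copy by
  `(2 - delta)/2`, so the noiseless AI inside the structure is exactly `delta`
  and total structure mass is preserved.
- Unilateral lesions (fractional scaling of one side of a structure), small
  rigid misalignment (per-subject translation/rotation jitter, default 0.5 mm
  / 0.5 degrees SD), and smooth additive noise.
- Handedness scores per HLD group drawn from truncated normals on [-100, 100]
  with group-specific means/SDs (left-dominant right-handed-leaning, etc.).

Noise is windowed to tissue support (a smoothed indicator of the noiseless
image above a small threshold) before clipping at zero. Unwindowed clipped
noise would create a half-normal background pedestal far outside the head,
which both distorts total tissue mass and drives spurious registration
displacements; real grey-matter segments have essentially empty backgrounds.

### 2.2 What it does not emulate

- Cortical folding, topology, or realistic grey-matter geometry; structures
  are smooth ellipsoids.
- MRI acquisition physics, bias fields, segmentation errors, or partial-volume
  tissue mixing beyond Gaussian blur.
- Inter-subject anatomical variability beyond rigid jitter and the injected
  volume effects (no subject-specific nonlinear shape differences).
- Correlated, spatially non-stationary noise; the noise field is stationary
  smoothed Gaussian noise within the tissue window.
- Any relation between handedness scores and the imaging data; they are drawn
  independently given the group.

Defaults are the "study conditions": acceptance-style experiments run the
generator with its default noise and jitter settings.

## 3. Numerical choices

- All computation in float64; volumes stored as float32 NIfTI.
- Grid default 49 x 48 x 48 at 3 mm (desk-scale stand-in for 1-2 mm
  whole-brain grids); odd x-dimension enforced.
- `FWHM = 2 sqrt(2 ln 2) sigma`, i.e. `sigma = FWHM / 2.3548`.
- Trilinear interpolation (`scipy.ndimage.map_coordinates`, order 1) for
  warping; `ndimage.zoom` for multiresolution transfer.
- Seeds: a single master seed feeds `numpy.random.SeedSequence`, which spawns
  independent per-subject and per-analysis streams; derived seeds are reduced
  modulo 2^31. Reruns with the same config and seed are byte-identical.
- Percentages are rounded half away from zero at one decimal to match
  conventional clinical-table rounding.

## 4. Limitations

- The demons registration is greedy and intensity-driven; it is
  diffeomorphic-in-practice (positive Jacobian enforced per step) but not a
  true stationary-velocity-field diffeomorphism, and it is tuned for
  desk-scale smooth phantoms, not real MRI.
- One template iteration is adequate for the synthetic cohorts but real data
  would need more iterations and an affine pre-alignment stage.
- Cluster-mean AI measured over a significant cluster is diluted by smoothing
  spill-over outside the true effect region; parameter-recovery checks
  therefore also report values over the intersection with the known ground
  truth structure.
- Permutation inference assumes exchangeability under the null; covariates
  are handled by keeping them attached to subjects, which is approximate when
  covariates are strongly group-imbalanced.
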