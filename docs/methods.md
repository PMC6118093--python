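# Methods

This note documents the models, parameters and numerical choices behind the
`fetmri` pipeline, and what its synthetic phantoms do and do not show about
real imaging data.

## The analysis chain

The pipeline estimates a binary classifier (recurrent brain metastasis vs
radiation injury; recurrence is the positive class) from paired CE-MRI and
static FET-PET volumes of each case:

reslice/filter → VOI definition → quantization → 42 features × 4 channels →
Mann-Whitney screening → best-subset AIC logistic regression (≤ 5 features) →
cross-validated metrics.

All stages are deterministic given the configuration and a master seed; the
cohort seed and the fold-shuffling seed are derived from the master seed.

### Image preparation

* CE-MRI is resliced to isotropic 1 mm (trilinear for intensities, nearest
  neighbour on the companion mask path). The output lattice preserves the
  node-to-node physical extent within one voxel. PET is not resliced by
  default (configurable).
* **LoG channel**: each axial slice is convolved with a 5×5 kernel sampled
  from the analytic Laplacian-of-Gaussian at σ = 0.5 px (= 0.5 mm on the 1 mm
  grid) and mean-subtracted so it sums to zero exactly; boundary handling is
  reflection. A zero-sum kernel annihilates constants, which is used as a
  self-check.
* **DWT3 channel**: one-level separable 3-D wavelet decomposition with the
  coiflet-1 filter pair; the reconstruction keeps only the subband that is
  high-pass along all three axes (HHH) and zeroes the rest, cropped back to
  the input shape. "High-frequency in all directions" has a second reading —
  every subband except the approximation — which is available behind
  `dwt3_mode="not_lll"`. The HHH reconstruction plus the complementary
  reconstruction recomposes the input to 1e-8, a perfect-reconstruction check
  run in the tests.
* No bias-field correction, no registration (inputs are assumed
  co-registered), and no global MR intensity normalization beyond the
  per-VOI quantization below — users should be aware that MR intensities are
  relative.

### VOI definition

* MRI VOI: supplied mask (ground truth for phantoms, a contour file for real
  data). When several lesions are present, only the largest (by voxel count)
  is analysed; ties keep the first and log a warning.
* PET VOI: connected component (26-connectivity by default; 6/18 available)
  of voxels with uptake ≥ 1.6 × background, where background is an explicit
  scalar (or the mean over a background mask) representing normal-brain
  uptake. Without a seed voxel the largest component is used. Lesions that
  never reach the threshold are "PET-negative" and fall back to the MRI mask
  resampled onto the PET lattice (nearest neighbour on physical coordinates).
* VOIs with fewer than 100 voxels (strictly < 100) are excluded per channel;
  the case is retained for the other channels, and exclusions are logged.

### Quantization and features

Within-VOI intensities are mapped to integer levels 1..64 between
`mean − 3·SD` and `mean + 3·SD` of the VOI (population SD; a sample-SD toggle
exists), `g = 1 + floor(64 (v − lower)/(upper − lower))` clamped to [1, 64].
A zero-SD VOI is flagged degenerate and maps to level 1.

The 42 features per channel:

* 5 statistics: Min, Mean, Max, SD of the raw intensities; Volume in mL.
* 4 histogram features on the 64-bin distribution: skewness, kurtosis (plain
  standardized 4th moment, not excess), entropy (log₂), energy.
* 6 GLCM features (homogeneity, energy, contrast, correlation, entropy,
  dissimilarity). Co-occurrences are counted over the 13 unique distance-1
  lattice directions, both orderings, pooled into a single symmetric matrix
  before normalization — equivalent to count-weighted averaging of
  per-direction matrices.
* 11 GLRLM features (SRE, LRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE,
  GLNUr, RLNU, RP) from maximal equal-level runs along the 13 directions;
  RP is normalized by 13·N_v so it lies in (0, 1] (a documented dialect
  choice).
* 3 NGLDM features (coarseness, contrast, busyness) in the
  neighbourhood-grey-tone-difference style: for each voxel with at least one
  in-VOI 26-neighbour, the absolute difference between its level and the mean
  level of those neighbours is accumulated per level; border voxels without
  in-VOI neighbours are skipped. Coarseness is guarded by ε = 1e-6.
* 11 GLZLM features (zone analogues of the GLRLM set) over 26-connected
  equal-level zones; ZP = N_z/N_v.
* 2 shape indices: Sphericity = (36πV²)^⅓/A and Compacity = V/(√π·A^{3/2}),
  with V from the voxel count and A from a triangulated isosurface. The exact
  Compacity convention varies between toolkits; the definition above is the
  adopted dialect.

**Surface area.** Marching cubes directly on the binary lattice chamfers
edges (a digital cube of side 10 measures ≈ 6 % low in area) and
staircase-facets curved surfaces (a digital ball measures ≈ 8 % high). The
implementation therefore meshes the zero level of the signed Euclidean
distance field, linearly upsampled 2× and smoothed with σ = 0.5 fine voxels:
axis-aligned faces are then reproduced almost exactly (cube sphericity 0.817
vs the analytic 0.806), while the ball's staircase bias remains (≈ 0.93).
Voxel-face counting was rejected because it overestimates A and biases
sphericity low for every shape.

**Undefined values.** Features that are undefined on degenerate VOIs (GLCM
correlation at zero marginal variance, NGLDM contrast/busyness with one
occupied level, histogram skewness/kurtosis at zero variance) are reported as
0 together with an explicit flag, never silently dropped.

All entropies use log base 2.

### Screening

Two-sided Mann-Whitney U per feature, recurrence vs injury. Exact enumeration
when n₁+n₂ ≤ 12 and there are no ties; otherwise the normal approximation
with mid-rank tie correction and continuity correction. No multiple-testing
correction by default, matching the single-feature p < 0.05 selection rule
the pipeline reproduces; a Benjamini-Hochberg option exists. Constant
features get p = 1. The combined candidate pool is the union of significant
MRI features and the top-8 most significant PET features; the top-k ranking
is restricted to significant features (ties on p broken by the larger
deviation of U from its null mean, then by name).

**Pool cap.** Exhaustive best-subset search over all subsets of ≤ 5 from a
pool of p features costs Σ C(p, 1..5) fits; p = 30 (≈ 1.7×10⁵ fits) is
desk-scale, but strongly separated synthetic cohorts can make most of the 126
MRI features significant. The pipeline therefore optionally caps the MRI pool
at the top-k significant MRI features (`mri_top_k`); the multi-seed studies
in the tests use k = 22, which also matches the size this screening step
produces on representative cohorts. With the cap disabled (default `None`)
the pool is exactly the significant set.

### Modelling

Maximum-likelihood logistic regression by Newton/IRLS on z-scored predictors
(convergence when the log-likelihood changes < 1e-10, at most 50 iterations;
the linear predictor is capped at ±30 for numerical stability). Coefficients
are reported on both the standardized and the raw scale (back-transformed);
AIC = 2k − 2 log L with k counting the intercept is invariant to the
standardization, which is verified numerically in the tests.

Quasi-complete separation is detected when any standardized coefficient
exceeds 15 in magnitude; because the capped linear predictor can make the
deviance plateau and mimic convergence, the magnitude check applies whether
or not the iteration formally converged, and runaway fits retain their last
stable iterate (used for predictions in cross-validation folds, with the fold
flagged). Separated or non-converged subsets are excluded from the AIC
ranking; if every subset is excluded the search raises.

The search enumerates subsets by increasing size and lexicographic feature
order and keeps the strictly best AIC (tolerance 1e-9), so exact ties resolve
to fewer variables, then alphabetical order. Fits are batched (chunked stacks
of design matrices solved with vectorised Newton steps) so the full combined
search runs in seconds.

One consequence of the separation rule worth knowing: on a *perfectly*
separable cohort the separating feature is excluded from the ranking, and the
selected model can be much worse than the obvious one. This mirrors the
behaviour of AIC selection with unpenalized likelihoods, where separated fits
have no finite MLE.

### Validation

Leave-one-out (deterministic), stratified 5-fold and 10-fold (shuffled with a
seed; fold class counts within one of proportional). Two modes:

* `fixed_subset` (default): the subset is selected once on all data and only
  the coefficients are refit per training fold — this validates "the
  resulting model" but inherits the optimism of the selection step;
* `nested`: screening, pool construction and subset search are repeated in
  every training fold; training folds where nothing is significant fall back
  to the intercept-only model.

The tests verify the expected ordering (fixed ≥ nested on average on
null-ish cohorts; apparent ≥ cross-validated). Metrics come from pooled
out-of-fold probabilities at threshold 0.5 (a Youden-optimal threshold is
available); AUC uses the rank statistic with mid-rank tie handling.

## The synthetic phantoms

Each case is a pair of co-registered 3-D volumes (default 48³ voxels at
1 mm; the multi-seed studies in the tests use 40³ at 7 mm radius to keep
runtimes short) containing a single lesion:

* **Geometry**: sphere of nominal radius `lesion_radius_mm`, boundary radius
  modulated per direction by a random degree-2..4 real spherical-harmonic
  field scaled by `shape_irregularity` (0 = ball; 1 = ±50 % radial
  excursion); the support is reduced to its largest 26-connected component.
* **Texture**: multiplicative stationary Gaussian random field inside the
  lesion (Gaussian-smoothed white noise, correlation length 2 mm,
  standardized, clipped at 3 SD, scaled by `texture_amp`); independent fields
  for MRI and PET with separate amplitudes.
* **Intensity**: PET plateau at `tbr_target ×` background (background 1.0,
  noise SD 0.05); MRI plateau at `mri_contrast ×` background (background 100,
  noise SD 5). Additive Gaussian noise per modality.
* **Class contrast** (the study conditions): recurrence lesions have
  irregularity 0.30 vs 0.18, MRI texture amplitude 0.40 vs 0.18, PET texture
  amplitude 0.30 vs 0.20 and TBR 2.5 vs 2.0. Per-case biological variability
  (SDs 0.10 / 0.10 / 0.12-equivalent / 0.35, radius SD 1.5 mm) makes the
  classes overlap so that single features discriminate imperfectly, as in
  real cohorts; the MRI texture contrast and the PET TBR contrast are
  deliberately complementary so the combined model can outperform both
  single-modality models.
* **Determinism**: each case's RNG seed is a CRC-32 hash of the cohort seed
  and the case id, so cohorts are pure functions of (n, prevalence, spec).
  Cohorts have exactly round-half-up(n × prevalence) recurrence cases.

What the phantoms do **not** emulate: acquisition physics (PET partial
volume, MRI bias fields, reconstruction artifacts), multi-lesion anatomy,
registration error, non-stationary or anisotropic texture, and any realistic
mapping from biology to intensity. Passing tests therefore demonstrate that
the *pipeline machinery* is correct and that it recovers class differences of
the kind it parameterizes — not that the clinical accuracies of any real
cohort would be reproduced.

One property of the adaptive mean ± 3 SD quantization deserves emphasis:
texture *amplitude* cancels out of the grey levels (the bins rescale with the
VOI SD), so GLCM entropy tracks the spatial correlation of the intensity
field, not its amplitude. Raising `texture_amp` over a white-noise floor
*lowers* GLCM entropy and raises GLCM energy while raising the raw intensity
SD — the tests assert these directions. Amplitude differences remain visible
to the screening stage through SD and related features.

## Problem sizes in the tests

The cross-validated multi-seed study runs 25 cohorts of 52 cases (21/31
split) on 40³ grids; screening calibration uses 50 null cohorts of 24 cases
on 32³ grids (point estimate ≈ 0.05 selected at α = 0.05); oracle equivalence
uses 200 random VOIs of up to 6³ voxels and 8 grey levels against brute-force
reference implementations at 1e-10. These sizes were chosen so the full suite
runs on a laptop-class single core in well under half an hour.

## Known limitations

* The NGLDM family follows the neighbourhood-grey-tone-difference
  definitions with 26-neighbourhoods restricted to the VOI; toolkits differ
  on border-voxel handling (skipped here) and on the exact Busyness
  denominator, so absolute values are dialect-dependent.
* Sphericity of curved digital shapes is biased a few percent low (staircase
  facets); comparisons *between* lesions at similar resolution are unaffected.
* `fixed_subset` cross-validation is optimistic by construction; the nested
  mode is the honest estimate and is recommended whenever the subset choice
  itself is part of the claim.
* With 126 correlated MRI features and no multiplicity correction, the
  screening stage over-selects under the null in the per-cohort sense (the
  5 % rate holds on average, with large cohort-to-cohort variance).
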