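# Methods

## Deformation model

All spatial transformations are diffeomorphisms parameterized by
stationary velocity fields (SVFs). A velocity field `v` (units:
voxels per unit time) generates the deformation `phi = exp(v)` as the
unit-time solution of `d phi(t)/dt = v(phi(t))` with `phi(0) = id`.
We compute the exponential by scaling and squaring: divide `v` by
`2^k`, add the identity, and compose the resulting near-identity map
with itself `k` times. The default `k = 7` keeps the scaled field in
the regime where `id + v/2^k` approximates the flow to well below
interpolation error for fields up to a few voxels in magnitude; the
test suite verifies agreement with 1024-step explicit Euler
integration to 1e-3 voxels on 16^3 smooth fields.

Deformations are stored as coordinate maps `phi(x)` (the source
location sampled for target voxel `x`), so composition is a pure
resample: `(phi_o o phi_i)(x) = phi_i(x) + u_o(phi_i(x))` with `u_o`
the outer displacement, trilinearly interpolated with edge-clamped
coordinates. Inversion in this parameterization is a sign flip of the
velocity, `exp(v)^-1 = exp(-v)`.

All field algebra happens in 0-based voxel-index coordinates with
vector components ordered like the array axes; the NIfTI affine is
carried as metadata only. This assumes inputs are affinely
pre-aligned and isotropically resampled, which is the standard state
of template-space neuroimaging data; cross-grid physical-space algebra
is deliberately out of scope.

### Direction convention

A single convention is used throughout: an SVF is the resampling flow
from the reference template toward a target anatomy,
`subject = warp(template, exp(v))` with `warp(I, phi)(x) = I(phi(x))`.
Concretely, registration is run with the *subject* (or the old
template) as the fixed image and the reference template as the moving
image. Under this convention

- the template-pair field uses the young template as moving and the
  old as fixed, and the aging flow applied to the young phantom
  enlarges its ventricles and shrinks its hippocampi;
- a subject that looks older than the reference projects *positively*
  onto the normal-aging field, matching the interpretation of positive
  aging scores as faster-than-normal aging.

The opposite pairing (subject as moving) would flip the sign of every
aging score; implementations mixing the two conventions silently
produce anti-correlated scores, which is why the package fixes one
convention and asserts its observable consequences in tests.

## Normal-aging field and regions

`v0` is the SVF between the 60- and 90-year healthy templates divided
by the 30-year gap (units: voxels/year), under a linear-atrophy
assumption — `v0` is constant across ages, and a subject's aging
component is modelled as `AS * v0`. Age-dependent aging fields are a
known limitation, not modelled here.

Regional analysis masks follow the FreeSurfer/SynthSeg label ids:
ventricles {4, 14, 15, 43}, hippocampi & amygdala {17, 53, 18, 54},
whole brain = any nonzero label. The ventricle *edge map* is the
difference between old- and young-template ventricle segmentations,
implemented as the symmetric set difference with a `growth_only`
flag restricting it to the enlargement shell (ventricles grow with
age, so old-minus-young is the dominant part; the symmetric
difference is the safe superset). A partial label set in a
segmentation is tolerated (anatomy and field of view vary); a region
whose labels are entirely absent raises an error.

## Score decomposition and outlier rejection

Per voxel, `AS = <v_subject, v0> / ||v0||^2` (years, signed) and
`ADS = ||v_subject - AS*v0||` (voxels, non-negative). Voxels with
`||v0|| <= eps = 1e-8` are marked invalid — `eps` only guards the
division; the substantive defence against unstable quotients is
quantile thresholding: within each region, voxels whose `||v0||`
falls below the regional q-quantile (linear-interpolation definition,
computed per region because the magnitude distribution differs
strongly across regions) are discarded. Voxels at or above the
threshold survive, so `q = 0` keeps every valid voxel. Regional
scores are arithmetic means over surviving voxels; ADS is aggregated
as the mean of voxel-wise residual norms (not the norm of the mean
residual), which preserves magnitude information when residual
directions vary.

The operating quantile is selected per region by sweeping
`q = 0, 0.1, ..., 0.9` and maximizing the R^2 of the ordinary
least-squares AS-versus-age fit over CN scans; ties go to the
smallest quantile (discarding the least data). AS is expressed in
years relative to the 60-year reference, so a CN cohort whose
morphological age tracks chronological age fits a slope of 1/yr
through zero at 60.

## Registration

The subject-to-template and template-pair SVFs are estimated by a
deterministic classical optimizer in the log-domain demons family:
sum-of-squared-differences data term, normalized demons force,
Gaussian (fluid-like) smoothing of each update (sigma 1.5 voxels at
full resolution), three resolution levels (x4, x2, x1; 100/60/30
iteration caps), and a backtracking line search on the data term that
removes the step-size parameter. With a segmentation mask, the data
term and the output field are restricted to the dilated foreground
(3 voxels), suppressing background-driven deformation. The optimizer
uses no randomness: identical inputs and settings give bit-identical
fields. Trained learning-based registration output can be substituted
at any point through 4-D NIfTI ingestion, and is expected to be both
faster and more accurate on real MRI; the built-in optimizer's
recovery contract (>= 95% SSD reduction and a projection coefficient
onto a planted field within [0.7, 1.3] on self-deformed phantoms) is
an engineering floor, not a claim about real-data accuracy.

## Sharpness metric

The entropy focus criterion over in-mask intensities `B_i`,
`EFC = -sum (B_i/B_max) ln(B_i/B_max)` with `B_max = sqrt(sum B_i^2)`,
is 0 when all energy sits in one voxel and maximal, `sqrt(N) ln
sqrt(N)`, for a uniform image. The normalized variant divides by that
uniform-image maximum — the unique normalization making the two
extremes exactly 0 and 1 on the closed range [0, 1]. Natural
logarithm; zero-intensity voxels contribute 0 (the `x ln x` limit);
any nonzero mask label counts as in-mask. A single-voxel mask has no
entropy scale and returns 0 for both values.

## Cohort statistics

Group comparisons operate on age-adjusted scores: an additive ANCOVA
`score ~ age + group` (common slope — the minimal model for removing
a shared age effect; an interaction model would conflate the group
effect with group-specific aging rates and is left to the user via
statsmodels directly), adjusted by `score - beta_age * (age - mean CN
age)` and centered by subtracting the CN mean, so CN sits at 0 and
the centering point cancels in all between-group contrasts. Pairwise
tests are Welch's independent t-tests by default (`equal_var=True`
recovers the classic pooled test), Bonferroni-corrected over the
pairs actually tested within one region and score; groups with fewer
than 5 scans are excluded from testing (reported, not crashed).
Cohen's d uses the pooled n-1 standard deviation regardless of the
t-test variant, with sign mean(first) - mean(second), and is banded
on |d|: medium [0.35, 0.65), large [0.65, 0.9), very large >= 0.9
(the 0.9 boundary is assigned upward). Significance stars follow the
conventional legend ns / * / ** / *** / **** at corrected p
thresholds 0.05 / 0.01 / 0.001 / 0.0001.

## Synthetic data

The phantom is a smooth-edged ellipsoidal brain (gray shell, brighter
white-matter core) with two lateral-ventricle ellipsoids, small
third/fourth-ventricle spheres, and hippocampus/amygdala blobs, on a
48^3 grid by default (configurable; 48^3 keeps every full-pipeline
test in seconds while leaving ~2-voxel aging deformations well
resolved). Label ids reuse the FreeSurfer/SynthSeg convention so the
built-in regions apply unchanged. The ground-truth one-year field
pushes a Gaussian shell at each ventricle boundary inward (growth
under resampling) and each temporal blob outward (shrinkage), peak
boundary speed 0.04 voxels/year — chosen so 30 years of aging
produces a deformation of about 2 voxels, the scale at which lateral
ventricle enlargement is conspicuous at 1 mm-class resolution — and
is exactly zero outside the brain.

Cohorts plant a known structure: aging score `as_slope * (age - 60)`
with `as_slope = 1/yr` (morphological age tracking chronological
age), group-specific disease offsets along a direction `w` built by
per-voxel Gram-Schmidt orthogonalization of a smooth random field
against the aging field (unit magnitude on its support, zero where
the aging field vanishes), and additive smooth Gaussian SVF noise
(smoothed white noise rescaled to component std 0.05 voxels by
default) standing in for registration error. Group sizes default to
CN 40, CDR0 20, CDR0.5 20, CDR1 15, CDR2 4 — a preclinical-heavy
composition with a deliberately undersized moderate-dementia group so
the small-group exclusion path is exercised. Ages are uniform on
group-specific ranges within 60–90.

What the generator does *not* emulate: MRI intensity nonuniformity
and noise, skull/scalp, anatomical variability between subjects
(every subject is a deformation of one template), subject-specific
(non-disease) residual deformation, and nonlinear aging trajectories.
Passing tests therefore demonstrate correctness of the decomposition,
selection and statistics machinery under known ground truth — not
that the scores separate clinical groups on real scans, which
additionally depends on template and registration quality.

## Numerical choices and degenerate inputs

- Trilinear interpolation everywhere (nearest-neighbour for labels);
  edge-clamped sampling; property tests assert on interior voxels
  (>= 2 from each face) since boundary values are clamp artifacts.
- Quantile definition: numpy's linear interpolation; survival rule
  `||v0|| >= threshold` so the q=0 sweep point keeps all valid voxels
  and n distinct magnitudes at q=0.5 keep exactly ceil(n/2).
- R^2-maximization ties resolved to the smallest quantile within a
  1e-12 slack (exact-fit sweeps produce floating-point near-ties).
- A constant score regressed on age reports R^2 = 0 (no variance to
  explain) rather than the indeterminate form.
- Registration line search halves the step at most 4 times; five
  consecutive non-improving iterations end a level with the best
  iterate kept. The data term is monotonically non-increasing by
  construction.
- Empty retained voxel sets, all-zero masked images, zero age
  variance, non-positive age gaps, and non-finite fields raise
  explicit `ValueError`s naming the offending quantity.

## Problem sizes

Default test and demonstration sizes: 16^3–24^3 grids for field
algebra properties, 48^3 for the phantom pipeline, 99-scan cohorts,
1000-repetition null calibration. These sizes make the entire suite
run in about a minute on one CPU while keeping every quantitative
contract (integration accuracy, recovery bands, calibration windows)
at its stated tolerance.

## Known limitations

- The residual score conflates disease-specific and subject-specific
  deformation; separating them needs a population model of healthy
  anatomical variability.
- Linear aging: a single `v0` for all ages.
- The classical registration stand-in is far slower and less accurate
  than trained networks on real MRI; its role here is deterministic
  desk-scale operation.
- Scores are aggregated in template space over template-derived
  region masks; subject-segmentation disagreement is not modelled.
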