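# Methods

This note records the models, conventions and numerical choices behind
`glossmvpa`, in the order data flows through the package.

## Stimulus rendering

**Geometry.** The object is a star-shaped surface r(u) = R₀(1 + a·g(u))
about its centroid, with g a seeded superposition of spherical harmonics
of order 1..n_modes (coefficients ~ N(0, 1/(1+ℓ)²)), normalized so
max|g| = 1. Defaults: R₀ = 40 mm (≈7° at the 650-mm viewing distance),
a = 0.12, n_modes = 5. Because a < 1 the radius is strictly positive, so
the surface is closed and star-shaped by construction; `make_potato`
rejects a ≥ 0.5 outright. The field g is tabulated once on a 257 × 513
(θ, φ) grid and sampled bilinearly; the surface is *defined* by that
deterministic table, which makes renders bit-reproducible and fast.

**Ray casting.** One primary ray per pixel from each eye (converged
cameras fixating the object center; vertical FOV 9°, 96² px default). The
first intersection with the radial surface is found by sampling the
implicit field F(x) = |x| − r(x/|x|) at 48 points between the
bounding-sphere entry/exit and bisecting the first sign change (48
iterations, ~1e-13 mm precision). Normals are central differences of F
(step 1e-4·R₀). There is no interreflection and no shadowing: the
environment is at optical infinity, so radiance depends only on the
reflected direction, which is the modeling assumption that makes the
condition manipulations exact.

**Conditions.** All four conditions image the geometry from the true eye
positions; `lookup_direction` is the single switch point. Mirror uses each
eye's own reflected ray ω = 2(n·V)n − V (V surface→eye); painted the
cyclopean eye's; anti-mirror the other eye's; flat copies one eye's mirror
image to both (eye chosen by a seeded coin flip, recorded in metadata).
Grazing surface points that are back-facing with respect to a *different*
lookup eye are excluded from the image. Per-pixel surface points, normals
and lookup directions are kept in `StereoPair.meta`, so the defining
identities (anti-mirror ↔ mirror eye swap; painted eye-invariance; flat
bitwise duplication) are machine-checkable, and the tests check them
exactly (== 0, not ≈ 0).

**Monocular pair.** The layered renderer composites a Lambertian diffuse
base (directional light + ambient) and the specular environment
reflection as separable layers sharing one silhouette. The matte image
rotates the specular layer about the image center (bilinear
interpolation) and masks it to the silhouette. This replaces an
interactive image-editing step with an exactly reproducible operation; it
is a modeling stand-in, not a pixel-level reproduction of any particular
edited stimulus set.

**Environment maps.** Three procedural equirectangular families
(gradient, Gaussian blobs, longitude bands; 128 × 256, seeded) stand in
for photographic light probes. They provide the angular structure the
manipulations need (smooth colored variation with localized features)
while keeping the package self-contained.

## Experiment design

Both sessions use 16-s blocks, TR 2 s: per run, 16 experimental blocks (4
conditions × 4, seeded pseudo-random order) and 7 fixation blocks (first,
last, and after experimental blocks 3, 5, 8, 11, 13). The binocular
session appends a 2-s response window to each experimental block (run
length 400 s = 200 TRs); the nonstereoscopic session does not (368 s =
184 TRs). Response windows are modeled as rest. Subjects complete 7-10
binocular and 8-10 nonstereoscopic runs (drawn uniformly per subject).

## Synthetic BOLD model

Voxels live on a 2.5 × 2.5 × 3 mm grid; ROIs are balls (default 14.5 mm
radius ≈ 590 voxels, comfortably above the 250-voxel selection) placed on
a ring, plus scattered background voxels so whole-brain QC statistics are
meaningful. Each ROI voxel belongs to one latent population —
shared-gloss {mirror, anti-mirror, glossy}, monocular-only {glossy},
binocular-only {mirror, anti-mirror}, structure {mirror, anti-mirror,
painted} — or is null. A voxel's response weight is drawn once per subject
as N(0, amplitude²) (percent signal change); zero-mean weights matter
because the pipeline removes each pattern's across-voxel mean, which would
erase any uniform activation. The population assignment is a property of
the subject, not the session (`assign_populations`), so cross-session
transfer sees the same voxels carrying the shared code. Hemodynamics are a
boxcar delayed by 4 s with a 1-TR linear ramp — deliberately matched to
the analysis's 4-s shift rather than a double-gamma HRF, so generator and
pipeline share assumptions. Noise is i.i.d. Gaussian per voxel and TR
(default SD 1% of baseline; optional AR(1)).

The structure population responds equally to all three stereoscopically
curved conditions and not to flat. This is what makes painted-vs-flat
decodable while leaving both gloss contrasts at chance, the signature the
recovery tests assert.

**Shared-subpopulation (transfer) model.** The example configuration
`GLOSS_TRANSFER_MODEL` uses f_shared = 0.05, f_mono_only = 0.20,
f_bino_only = 0.50, amplitudes 0.15 / 0.15 / 0.40 %, noise 1%. Two
regimes were explored before freezing it. With strong signals the SVM
separates training classes with wide margins and its intercept lands
midway between them; testing on the weaker session then puts *every*
pattern on one side (balanced accuracy exactly 0.5), and the transfer
asymmetry comes out inverted. In the weak-signal regime (single-subject
accuracies in the realistic 55-85% range) transfer is graded, and the
asymmetry direction is controlled by which population dominates the
trained weights: a binocular-trained classifier latches onto the strong
specialized binocular-only population, silent for monocular gloss, so
binocular→monocular transfer fails, while a monocular-trained classifier
weights the broad monocular population including the shared subset, which
also responds binocularly, so monocular→binocular transfer succeeds.
These amplitudes place the model in that regime; the tests assert the
direction of the asymmetry, not its magnitude.

**Run QC.** The QC statistic is the variance (ddof = 1) of the whole-brain
mean time course expressed in percent change about its own mean; runs
above 0.23 are excluded. A sinusoidal drift of amplitude A% contributes
A²/2, so `inject_global_drift` at 1% is flagged and 0.01% is retained, the
calibration the tests use.

## Pattern extraction

Per ROI, voxels are ranked by the pooled-variance two-sample t of
shifted experimental-window TRs vs shifted fixation-window TRs (no
nuisance model; the contrast never sees condition labels, preserving
cross-validation validity); the top 250 are kept, or all positive-t voxels
if fewer. Each voxel's full run time course is z-scored (per run, per
voxel — which also makes extraction invariant to per-voxel gain and
offset); block windows are shifted 4 s and their 8 TRs averaged; each
pattern's across-voxel mean is subtracted. The alternative reading of the
baseline-removal step — subtracting each voxel's across-block mean per run
— is available as `normalization="voxel_run_mean"` but is not the default:
the per-pattern mean is the reading that removes condition- and run-level
baseline offsets at the single-pattern level.

## Decoding

Linear SVM (libsvm; C = 1, tol = 1e-3) on the extracted patterns;
class weights inverse to class frequency when the training classes are
unequal; ties at decision value 0 go to the positive class. Leave-one-run-
out folds never contain the test run's patterns in training (asserted on
fold bookkeeping). Confusion counts are pooled over folds with the glossy
side of each contrast as "signal".

**Accuracy convention.** Reported accuracies and all permutation nulls use
the class-balanced (macro-averaged) accuracy (TPR + TNR)/2, which equals
correct/total for every equal-class contrast. For the 2-vs-1 contrast it
is the only unbiased choice: on linearly separable shuffled data a
max-margin classifier predicts the majority class about two-thirds of the
time regardless of class weights or C (measured here across C = 0.01-10),
which would center a plain-accuracy null near 0.556 rather than 0.5.

**Transfer.** Cross-session transfer trains one model on all of the
training session's patterns and tests once on the other session's
patterns, with voxels selected from the training session and applied to
both (the per-session-intersection alternative is not implemented; the
single-selection rule keeps the feature space identical by construction).
Within-session transfer between contrasts sharing a condition (painted)
uses leave-one-run-out folds (`transfer_cross_validate`): training on all
runs would memorize the shared blocks and test on them.

## Permutation inference

The null for a decoding analysis shuffles condition labels within each run
independently for every subject and re-runs the analysis; the recorded
statistic per repetition is the across-subject mean, and the significance
boundary is the one-tailed 95th percentile over repetitions (averaged
across ROIs when several are analyzed). Three granularities are
implemented; measurement against the five published boundaries this
pipeline targets decided the default:

- `per_fold` (default): labels of the tested conditions are redrawn for
  every cross-validation fold — "shuffling labels per test". Folds stay
  decorrelated; measured boundaries 52.2-53.0% for 12 subjects.
- `per_rep`: one draw per repetition, whole CV re-run on it. The shared
  labels couple folds (a shuffle that happens to align with noise helps
  every fold), widening boundaries by ~+0.5-0.9 pp.
- `shuffle_scope="all"`: per-rep draw over all 16 labels, additionally
  randomizing which blocks enter the contrast; widest.

The transfer null shuffles the training and the test labels
*independently* (one split, no folds): with a shared draw, blocks present
in both sets would keep their training identity at test and be memorized,
biasing the null far above 0.5. The index null shuffles all labels per
fold, with the *same* draw feeding all three d′ terms within that fold, so
the shared mirror-vs-anti-mirror baseline stays correlated with the other
terms — the coupling that makes a difference null tighter than its parts.

d′ uses z(H) − z(F) from fold-pooled counts with rates clipped to
[1/(2N), 1 − 1/(2N)]; the alternative 2·z(accuracy) convention is
available as `dprime_from_accuracy`. Permutation seeds derive from a
single master seed (per-ROI streams via `SeedSequence.spawn`), so every
null is bit-reproducible.

Group inference is a one-sample t of per-subject values against the
permutation boundary, one-tailed, Bonferroni-corrected across ROIs; the
2 × n-ROI repeated-measures ANOVA (statsmodels `AnovaRM`) with Tukey HSD
on the index-by-ROI cells compares the two indices across regions. Both
handle the zero-variance degenerate cases (identical values → t or F = 0;
ceiling accuracies → infinite t, significant) explicitly.

## Searchlight

Spheres of 8 mm radius on the anisotropic grid (center-to-center distance
≤ radius; an interior sphere holds 113 voxels — the lattice count under
this rule). Patterns are extracted once for the whole volume; per center,
the neighborhood's columns are re-mean-removed locally and decoded with
the same LORO SVM, without the top-250 selection (the sphere is the
feature set); accuracy is written at the center. Group maps are tested
per voxel against 0.5 (one-tailed t), thresholded at α = 0.05, formed into
26-connected clusters, and clusters below 4 voxels are dropped — the
grid-native analogue of a 25 mm² surface criterion (4 × 6.25 mm²
in-plane); both the radius and the minimum extent are parameters.

## Problem sizes and what the tests do (and do not) show

The acceptance computations use 12-subject null cohorts, 1,000 shuffles
per analysis, boundaries averaged over two simulated ROIs (the null
boundary is a property of the design and analysis, not of ROI content;
averaging only reduces Monte-Carlo scatter, which is ~0.1 pp on a
1,000-rep 95th percentile). Recovery tests use 20 single-subject
replicates; the searchlight false-positive check uses 20 null subjects on
a compact mask; the index nulls use 600 repetitions per ROI. Inside the
permutation loops the SVM is solved through scikit-learn's bundled libsvm
directly with precomputed Gram matrices (decision values formed from the
returned dual coefficients, verified against the public `SVC` API at
import, with automatic fallback).

The generator emulates the *logical* structure of the measurement —
population-selective condition responses, run structure, hemodynamic
delay, baseline drifts — but not several properties of real fMRI: noise
is spatially and temporally white by default (real noise correlations
reduce the effective feature dimensionality, which slightly narrows
shuffled-label nulls and changes overfitting behavior), voxel sampling of
neural populations is linear and stationary across sessions, and there is
no head motion, physiology or coregistration error. Passing tests
therefore certify the analysis chain — its arithmetic, its invariances,
its null calibration, and its ability to recover planted representational
structure — not the biological fidelity of any particular simulation.

## Known limitations

- The renderer is exact for the radial-surface class it defines but does
  not model interreflection, occlusion of the environment by the object,
  or tone mapping; images are for stimulus-structure work, not photometry.
- The 2-s response windows of the binocular session are modeled as rest.
- `compare_indices_anova` requires a complete subject × ROI × index table;
  subjects with skipped folds must be handled upstream.
- Cross-session transfer assumes voxel correspondence across sessions
  (same grid, no realignment error), the best case for detecting shared
  representations.
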