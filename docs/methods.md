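# Methods

This note documents the models, parameter choices and known limitations of
the package, in the spirit of a methods appendix. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic phantoms

**Anatomy.** A phantom is a concentric shell model: background, skull,
intradural CSF, a cortical grey-matter ribbon of constant radial width,
white matter, and two ellipsoidal lateral ventricles. The pial surface is
perturbed by periodic indentations ("sulci") whose profile is a clipped
cosine — flat-bottomed troughs of depth equal to the configured amplitude,
separated by narrow ridges — laid out as latitude rings so fold spacing is
uniform over the surface (azimuthal folds would collapse to sub-voxel size
near the poles). The atlas partitions the cortex into 8 angular sectors,
white matter into 4 sectors, a periventricular ring into 8 deep-grey
"anatomies" (4 per side, named caudate/thalamus/putamen/pallidum per side
for readability), and the two ventricles. The model is deliberately
schematic: the downstream methods need tissue interfaces, stable regional
labels and exactly-known injury volumes, not anatomical realism.

Defaults: 96³ voxels at 1 mm for single-phantom experiments
(brain semi-axes 30/36/30 mm); a 64³ configuration (semi-axes 20/24/20 mm,
ventricle semi-axes 5.5/9.5/5.5 mm) for cohort-scale runs, chosen so a
139-subject cohort streams through every stage in minutes. The cohort
problem sizes used by the tests and the acceptance script are stated in
their outputs.

**Inter-subject variability.** Every cohort subject receives a jittered
copy of the base configuration: brain semi-axes (relative sd 2%), cortical
thickness (4%), per-side ventricle semi-axes (8%), sulcal amplitude (15%)
and a random sulcal phase. This variability is what gives the normative
statistics and the ventricle shape model something real to estimate;
without it control variances collapse to measurement noise and z-scores
are undefined.

**Injuries.** Lesions are spheres (clipped to their parent tissue) with a
per-modality multiplicative contrast (defaults: T1 ×0.6–0.8, T2 ×1.5–1.9
for WM lesions, i.e. T2-hyperintense, T1-hypointense). Ventricular
enlargement grows the ventricle mask voxel-by-voxel into white matter,
restricted to a directional cone (configurable width) and closest-first
within it, until the target added volume is reached to within one voxel —
a compact directional lobe with exactly known volume. Cortical thinning
rescales the ribbon from the pial surface inward in selected sectors; the
stripped voxels become white matter. A centre sampled on the template
anatomy may be snapped up to 3 mm onto the jittered subject's tissue.

**Injury co-occurrence.** The sampler draws the three injury types
independently at patient-level rates 0.68 (enlargement), 0.55 (lesions)
and 0.30 (cortical thinning), matching the prevalence ordering reported
for unilateral-CP cohorts; independence then makes enlargement accompany
lesions in ~68% of lesion patients, above the >60% co-occurrence such
cohorts show. Thinning affects 2–3 sectors per affected patient,
enlargement adds 0.5–2.5 mL per side (capped so the lobe cannot reach the
cortical ribbon of the compact cohort phantom, which would corrupt
thickness measurements there).

**Acquisition.** Intensity = per-tissue mean × polynomial bias field,
then Rician corruption `sqrt((s+n₁)² + n₂²)`, n₁,n₂ ~ N(0,σ). Default
tissue means give a T1-like contrast (WM bright, CSF dark, skull
brightest) and a T2-like contrast (CSF bright, WM dark). σ = 5 on means of
40–220 puts the brightest tissue near SNR 30–45; σ = 8 gives SNR 20 for
white matter on T1. Bias amplitude 0.2 (fraction of the mean) with a
random polynomial of order 2 is the default cohort condition.

**Clinical scores.** Each of the six scores is a sparse negative linear
function of true injury biomarkers plus small covariate effects and
Gaussian noise. Feature weights follow clinical magnitude conventions
(~0.1–1 per mL of lesion or enlargement, ~1–15 per z-unit of shape
change), rescaled so each selected feature contributes comparable
variance; only features with genuine cohort variability (nonzero in ≥6%
of subjects) are eligible. Covariate effects are scaled to a modest
fraction of the biomarker signal, and the noise sd is calibrated on the
full predictable variance so the generated score has the requested R²
(default 0.7) against its own linear predictor — with covariates included
in the calibration the maximum attainable test-set correlation is √R².

## Preprocessing

* **Skull stripping**: Otsu threshold → morphological opening (ball r=2)
  → largest connected component → hole filling → closing; the intradural
  CSF band (second Otsu on the sub-threshold intensities, components
  touching the brain) is folded in. Failure (no component ≥1% of the
  grid) raises an error rather than guessing.
* **Bias correction**: log-intensities inside the mask are modelled as a
  per-tissue offset (4 intensity clusters, re-assigned each of 10
  iterations by a deterministic 1D k-means) plus a polynomial of total
  degree 3; the converged polynomial is divided out. The cluster offsets
  keep the field from absorbing tissue contrast — the same role histogram
  sharpening plays in N4-style correctors. This is a surrogate with the
  same contract as N4, not a re-implementation.
* **MCDE denoising**: explicit level-set scheme with staggered
  (face-centred) fluxes — forward differences for the gradient, backward
  for the divergence — because naive central differencing decouples the
  odd/even lattice and barely removes voxel-scale noise. Conductance κ
  defaults to 2× the image sd; Δt = 0.0625 is the 3D explicit stability
  bound.
* **Registration**: direct multi-resolution (4×, 2×, 1×) minimisation of
  mean-squared intensity error over rigid (optionally + scale) parameters
  with Powell's method; parameters are expressed in mm and degrees about
  the fixed-image centre so unit steps are commensurate. Pyramid levels
  are Gaussian anti-aliased before decimation — without this the folded
  cortex aliases at coarse scales and the cost surface develops false
  minima. Phantom cohorts share one spatial frame, so the pipeline runs
  with registration off by default; the operation is exercised by its own
  tests.

## Segmentation and lesions

A bivariate Gaussian mixture (CSF/GM/WM) with spatially varying priors —
Gaussian-smoothed (FWHM 4 mm) tissue masks of the subject's own control
anatomy, standing in for registered atlas tissue probability maps. The
CSF prior keeps a floor of 0.15 within 10 mm of the ventricles so
pathological enlargement into periventricular white matter can be claimed
by the CSF class. The MRF is realized as mean-field Potts smoothing of
the posteriors (6-neighbourhood, β default 0.5) folded into each E-step;
EM stops when the mean absolute posterior change falls below 1e-4. The
recorded convergence curve is the observed-data mixture log-likelihood,
the quantity EM cannot decrease at β=0 (with β>0 it is a
pseudo-likelihood).

Lesion classes are added in a second phase after the healthy-tissue fit
converges: candidate voxels are Mahalanobis outliers (distance > 3) to
every healthy class, inside the parent tissue's prior core (prior > 0.8,
adapted downward for thin structures), and — for WM lesions — beyond the
parent's T2 mean + 2 sd. Components are seeded from the candidates' own
moments (falling back to parent mean + 2 sd on T2) with a small uniform
spatial prior ε = 0.02 inside the parent core, then EM refines all
classes together. Components claiming fewer than 5 voxels are dissolved
into their parent. The core gating matters: partial-volume shells at
tissue interfaces are outliers to every class but are not lesions, and
without the gate the lesion component migrates onto them. A Mahalanobis
outlier flag (threshold 3) is retained as a diagnostic for voxels no
lesion component claimed. Covariances are ridge-floored against the
global intensity scale so a collapsing component can never produce
degenerate likelihoods. With T1-only input the mixture runs univariate
and the model records `bivariate_ = False`; lesion performance contracts
are only asserted for bivariate input.

## Cortical morphometry

Thickness is the sum of Euclidean distances from each GM voxel to the WM
interface and to the pial interface, minus one mean voxel spacing
(centre-to-centre offset) — an O(N) surrogate for streamline thickness
that is accurate on ribbon geometry. Curvature is the divergence of the
normalised gradient of the (Gaussian-smoothed, σ=1 mm) signed distance
embedding of the pial surface; this is the sum of principal curvatures
(2/R on a sphere). A Gaussian-curvature variant
(`curvature_kind="gaussian"`, units mm⁻²) is available behind a switch:
the two conventions coexist in the literature and in figure axis labels,
so both are implemented; the default is mean curvature. Sulcal depth is
the distance from the ball-closing hull (radius 15 mm, computed via
distance transforms) of the pial-bounded interior to each surface voxel;
the hull is eroded one voxel first so surface voxels in contact with it
read ≈0. Regional summaries are means over surface voxels (full-ribbon
voxels for thickness); regions with <20 surface voxels are flagged
unreliable. Normative statistics require ≥10 controls and error out on
zero variance rather than emitting infinite z-scores.

## Ventricle shape model

Shapes are truncated signed distance fields (negative inside, saturated
at ±4 mm) on the shared grid. Truncation is essential: untruncated SDFs
are dominated by far-field distances and PCA then ignores surface-local
shape differences. Extraction takes CSF voxels connected to the
(3-voxel-dilated) ventricle atlas region, grown through contiguous CSF
(bounded by 12 voxels reach and the side's hemisphere) so enlargement
lobes extending past the atlas region are captured; the largest component
is kept. The PCA retains the smallest mode count reaching 95% variance;
eigenvector signs are fixed (largest-magnitude component positive).
Reconstruction clamps each coefficient at ±3√λ — the "healthy
variability envelope"; enlargement is the region inside the patient
ventricle but outside the reconstruction, each voxel attributed to the
nearest deep-grey anatomy label, so attributed volumes sum to the total
exactly. Left and right are modelled separately.

## Injury rules and prevalence

"Greater than 0 mL" is operationalized as greater than one voxel volume:
under discretisation, exact zero is unattainable and a floor makes the
rule meaningful; the false-positive characterisations this still permits
(controls with ~0.01 mL residua get flagged) mirror what mesh-alignment
errors do in real cohorts, and the prevalence summary therefore reports
cohort-wide and patients-only denominators side by side.

## Association models

The solver, its KKT conditions and the λ path are described in the
README. Design choices worth recording:

* The sign constraint applies only to injury biomarkers. Covariates are
  unpenalized and unconstrained — age effects on function are positive,
  and constraining them would be wrong.
* Post-selection inference is an unconstrained OLS refit on the selected
  support: standard errors, t-test p-values and adjusted R² are
  quantities a pure LASSO fit does not provide. The refit is on raw
  feature scales so coefficients read as "score change per mL" / "per
  z-unit".
* The train/test split is 75/25 of complete cases, stratified by sex
  only, rounding toward train; the penalty path is 100 log-spaced values
  from λ_max down to 10⁻³λ_max with 10-fold seeded CV minimising mean
  squared error. All of fraction, folds and path length are
  configuration parameters.
* Relative mean error is defined on cohort means,
  100·(mean(pred) − mean(obs))/mean(obs).
* Nested-model F-tests refit the reduced (single-family + covariates)
  model on the same rows; degenerate nestings (empty family, or nothing
  dropped) are flagged as skipped rather than fabricating a statistic.

## Numerical choices and degenerate inputs

Posteriors are renormalised every E-step (checked to 1e-6). Coordinate
descent converges at max coefficient change < 1e-7 (standardized scale)
and is verified against an exact active-set enumeration oracle for small
p. Flat images refuse registration; constant images refuse
normalisation; empty masks, missing normative entries, zero control
variance, mixed-side SSM training sets and CSF-free segmentations all
raise typed errors. Ties in enlargement growth are broken by voxel index
(lexicographic) so the generator is bit-reproducible.

## What the phantoms do and do not show

Passing tests demonstrate that every stage does what it claims on
geometry it can in principle handle: exact-volume injuries, Gaussian-ish
tissue classes, a shared spatial frame, covariates with known effects.
They do not demonstrate robustness to real-brain gyrification, non-affine
anatomical variability, multi-site intensity distributions beyond a
categorical covariate, motion or reconstruction artefacts, or lesion
textures beyond uniform contrast spheres. Two measured interactions on
phantoms are worth knowing: large ventricular lobes approaching the
cortical ribbon bias regional thickness upward in the overlying sector
(bounded by capping sampled enlargement volumes), and lesions closer than
~2 mm to a tissue interface lose their rim to the prior-core gating, so
very small or superficial lesions are under-segmented — consistent with
the lower specificity/sensitivity reported for WM/GM lesions
respectively by lesion-as-outlier methods on real data.
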