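# cpinjury

Automated quantification of three aetiologies of brain injury from
structural MRI — cortical shape abnormality, white/grey matter lesion
burden, and localized ventricular enlargement — together with
sign-constrained regression models that link those imaging biomarkers to
clinical scores. The package is aimed at researchers studying
structure–function relationships in paediatric brain injury (e.g.
unilateral cerebral palsy), and at method developers who need a fully
synthetic, ground-truthed testbed for such pipelines: every stage runs
end-to-end on simulated 3D brain phantoms whose injuries are known
exactly, so the whole chain is quantitatively verifiable without any
patient data.

## What it computes

Given T1- and T2-like volumes for a cohort of controls and patients, the
pipeline performs:

1. **Preprocessing** — skull stripping (thresholding + morphology, keeping
   brain tissues and intradural CSF), multiplicative bias-field removal (a
   tissue-adaptive polynomial log-domain fit), edge-preserving denoising by
   the modified curvature diffusion equation
   `I ← I + Δt·|∇I|·div(c(|∇I|)∇I/|∇I|)` with `c(g) = 1/(1+(g/κ)²)`,
   percentile intensity normalisation, and multi-resolution affine
   registration.
2. **EM/MRF tissue + lesion segmentation** — a bivariate (T1,T2) Gaussian
   mixture with spatially varying tissue priors and mean-field Potts
   smoothing of the posteriors (coupling β); lesions are handled
   *as outliers*: extra mixture components seeded at the T2-hyperintense /
   outlier tail of white and grey matter capture voxels the healthy
   classes cannot explain. Output: per-region lesion volumes in mL.
3. **Cortical morphometry** — voxel-based cortical thickness (symmetric
   nearest-boundary distances), curvature (divergence of the pial surface
   normal, `div(∇φ/|∇φ|)`), and sulcal depth (distance from the
   morphological closing hull of the cortex). Regional means are converted
   to absolute z-scores `|z| = |x−μ|/σ` against a normative control
   cohort.
4. **Ventricle statistical shape model** — PCA over truncated signed
   distance fields of control lateral ventricles; a patient's ventricle is
   projected onto the retained modes with coefficients clamped at ±3√λ
   (the *nearest healthy shape*), and voxels inside the patient ventricle
   but outside that reconstruction are the localized enlargement,
   attributed in mL to the nearest deep grey matter anatomy.
5. **Binary injury rules and prevalence** — lesion/enlargement present if
   any regional volume exceeds one voxel; cortical malformation if any
   regional shape |z| > 2.5; cohort prevalence as an 8-cell Venn
   decomposition.
6. **Structure–function models** — for each of six clinical scores (AHA,
   BRIEF, SDQ, TVPS, WR, VOC), a LASSO with **non-positive** coefficients
   on all injury biomarkers (injury can only reduce function) and free,
   unpenalized age/sex/scanner-sequence covariates:

   minimise (1/2n)‖y − Xβ − Zγ‖² + λ·Σ|βⱼ|  subject to βⱼ ≤ 0,

   solved by coordinate descent with the one-sided soft threshold
   `βⱼ ← min(0, (ρⱼ+λ)/cⱼ)`; λ is chosen by seeded 10-fold
   cross-validation over a 100-point log path, the selected support is
   refitted by OLS (coefficients, standard errors, p-values, adjusted R²),
   models are validated on a held-out 25% test set via Pearson r with
   Fisher-z confidence intervals and Bonferroni correction (0.05/6 =
   0.008), and nested-model F-tests compare the full model against
   cortical-only / lesion-only reductions.

The synthetic-data generator (`cpinjury.phantom`) is first-class: it
builds sulcated ellipsoid-shell brain phantoms with per-subject anatomical
variability, injects lesions / enlargement / thinning with exact
ground-truth volumes, emulates MR acquisition (per-tissue intensities,
polynomial bias field, Rician noise), and generates clinical scores as
sparse negative linear functions of the true injuries.

## Worked example

```python
from cpinjury import PipelineOptions, run_cohort_pipeline

opts = PipelineOptions(n_controls=12, n_patients=12, cv_folds=5, seed=3)
opts.acquisition.bias_amplitude = 0.2
result = run_cohort_pipeline(opts)

print(result.prevalence.totals)
for score, report in result.evaluations.items():
    print(f"{score}: r = {report.pearson_r:.3f}  "
          f"CI = ({report.ci_low:.2f}, {report.ci_high:.2f})  "
          f"p = {report.p_value:.4f}")
```

On this small 24-subject cohort the run printed:

```
{'cortical': 9, 'lesion': 13, 'enlargement': 13}
AHA: r = 0.925  CI = (0.23, 1.00)  p = 0.0243
BRIEF: r = 0.077  CI = (-0.86, 0.90)  p = 0.9022
SDQ: r = 0.503  CI = (-0.68, 0.96)  p = 0.3881
TVPS: r = 0.862  CI = (-0.08, 0.99)  p = 0.0600
WR: r = -0.638  CI = (-0.97, 0.56)  p = 0.2470
VOC: r = 0.842  CI = (-0.16, 0.99)  p = 0.0735
```

meaning 9/13/13 of the 24 subjects were flagged with cortical, lesion and
enlargement injury respectively; the held-out correlations between
predicted and simulated clinical scores reach 0.84–0.93 for scores whose
generating injuries were well measured, while a 6-row test set makes
individual correlations (and their Fisher-z intervals) very volatile —
cohort-scale runs with 139 subjects give stable per-score medians in the
0.6–0.9 range at a generative R² of 0.7.

The same pipeline is scriptable stage by stage from the shell:

```bash
cpinjury simulate --config config.json --out run/
cpinjury preprocess --out run/
cpinjury segment --out run/
cpinjury shape --out run/
cpinjury ventricles --out run/
cpinjury assemble --out run/
cpinjury model --out run/
cpinjury report --out run/
```

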