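"""End-to-end cohort pipeline: simulate -> preprocess -> segment -> shape ->
ventricles -> assemble -> model -> report.

Controls are processed first (two passes are needed: normative shape
statistics and the ventricle shape model are built from controls before
any subject can be scored against them), then patients are streamed one at
a time so cohorts of arbitrary size fit in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from .biomarkers import (
    ENLARGEMENT_PREFIX,
    LESION_PREFIX,
    SHAPE_PREFIX,
    classify_injury,
    cohort_prevalence,
    feature_names_for_atlas,
)
from .cortical import NormativeZScorer, compute_shape_maps, summarize_regions
from .phantom import (
    AcquisitionSpec,
    AnatomyJitter,
    GroundTruth,
    InjurySampler,
    PhantomConfig,
    ScoreGeneratorSpec,
    Subject,
    build_anatomy,
    cohort_manifest,
    default_score_generators,
    realize_subject,
    simulate_clinical_scores,
    simulate_cohort,
)
from .preprocess import (
    BrainMask,
    correct_bias,
    denoise_mcde,
    normalize_intensity,
    strip_skull,
)
from .segmentation import (
    EMMRFSegmenter,
    detect_lesions,
    make_tissue_priors,
    regional_lesion_volumes,
)
from .ventricles import VentricleSSM, extract_ventricle_shape, localize_enlargement
from .volume import Label, RegionAtlas, RegionClass

__all__ = ["PipelineOptions", "SubjectResult", "CohortResult", "run_cohort_pipeline",
           "process_subject", "truth_biomarker_row"]


@dataclass
class PipelineOptions:
    """Stage parameters of the cohort pipeline."""

    n_controls: int = 44
    n_patients: int = 95
    base_config: PhantomConfig = field(default_factory=PhantomConfig.cohort_default)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    injury_sampler: InjurySampler = field(default_factory=InjurySampler)
    jitter: AnatomyJitter = field(default_factory=AnatomyJitter)
    # preprocessing
    bias_correction: bool = True
    bias_order: int = 2
    denoise_iterations: int = 3
    # segmentation
    mrf_beta: float = 0.5
    em_max_iter: int = 50
    # shape / ssm
    hull_radius_mm: float = 15.0
    ssm_variance: float = 0.95
    # scores and models
    score_target_r2: float = 0.7
    score_features: int = 3
    train_fraction: float = 0.75
    cv_folds: int = 10
    cv_lambdas: int = 100
    fit_models: bool = True
    seed: int = 0


@dataclass
class SubjectResult:
    subject: Subject
    shape_summary: pd.DataFrame
    lesion_volumes: pd.DataFrame
    ventricle_shapes: dict
    truth_row: dict
    voxel_volume_mm3: float


@dataclass
class CohortResult:
    manifest: pd.DataFrame
    biomarkers: pd.DataFrame  # measured features + covariates, subject_id index
    truth_biomarkers: pd.DataFrame
    scores: pd.DataFrame
    prevalence: object
    prevalence_patients: object
    models: dict
    evaluations: dict
    comparisons: dict
    normative: NormativeZScorer
    ssm: dict
    bonferroni: float


def process_subject(
    subject: Subject,
    opts: PipelineOptions,
    priors_cache: dict | None = None,
) -> SubjectResult:
    """Run one subject through preprocessing, segmentation and shape stages."""
    from .phantom import inject_injuries, simulate_mri
    import copy as _copy

    # one anatomy build serves both the subject frame and the tissue priors
    anatomy = build_anatomy(subject.config if subject.config is not None else opts.base_config)
    # priors come from the subject's own (control) anatomical frame — the
    # stand-in for atlas tissue probability maps registered to the subject
    priors = make_tissue_priors(anatomy)
    truth = inject_injuries(anatomy, subject.injury, snap_mm=3.0)
    acq = _copy.deepcopy(opts.acquisition)
    acq.seed = subject.acq_seed
    t1, t2 = simulate_mri(truth, acq)
    atlas = truth.atlas

    mask = strip_skull(t1)
    volumes = {}
    for name, img in (("t1", t1), ("t2", t2)):
        if opts.bias_correction:
            img = correct_bias(img, mask, order=opts.bias_order)
        if opts.denoise_iterations > 0:
            img = denoise_mcde(img, iterations=opts.denoise_iterations)
        volumes[name] = normalize_intensity(img, mask)

    seg_model = EMMRFSegmenter(beta=opts.mrf_beta, max_iter=opts.em_max_iter).fit(
        volumes["t1"], volumes["t2"], mask, priors
    )
    seg = seg_model.result_

    lesions = detect_lesions(seg_model)
    lesion_table = regional_lesion_volumes(lesions, atlas, seg.spacing)

    maps = compute_shape_maps(seg, mask, hull_radius_mm=opts.hull_radius_mm)
    shape_summary = summarize_regions(maps, atlas)

    shapes = {
        side: extract_ventricle_shape(seg, atlas, side, subject_id=subject.subject_id)
        for side in ("left", "right")
    }

    return SubjectResult(
        subject=subject,
        shape_summary=shape_summary,
        lesion_volumes=lesion_table,
        ventricle_shapes=shapes,
        truth_row=truth_biomarker_row(truth, opts.jitter),
        voxel_volume_mm3=truth.voxel_volume_mm3,
    )


def truth_biomarker_row(truth: GroundTruth, jitter: AnatomyJitter) -> dict:
    """Ground-truth biomarker vector with the measured table's schema.

    Thickness features are expressed in pseudo-z units (cortical loss over
    the nominal inter-subject thickness sd implied by the anatomy jitter),
    lesion and enlargement features in true mL.
    """
    atlas = truth.atlas
    row: dict = {}
    base_t = truth.config.gm_thickness_mm
    nominal_sd = max(base_t * jitter.gm_thickness_rel_sd, 1e-6)
    for rid in atlas.ids_of_class(RegionClass.CORTICAL):
        name = atlas.name_of(rid)
        loss = base_t - truth.true_thickness_mm.get(rid, base_t)
        row[f"{SHAPE_PREFIX}{name}__thickness"] = abs(loss) / nominal_sd
        row[f"{SHAPE_PREFIX}{name}__curvature"] = 0.0
        row[f"{SHAPE_PREFIX}{name}__sulcal_depth"] = 0.0
    lesion_by = {
        (int(r.region_id), r.lesion_class): float(r.volume_mL)
        for r in truth.true_lesion_volumes.itertuples()
    }
    for rid in atlas.ids_of_class(RegionClass.CORTICAL) + atlas.ids_of_class(RegionClass.DEEP_GREY):
        row[f"{LESION_PREFIX}{atlas.name_of(rid)}__GM"] = lesion_by.get((rid, "GM-lesion"), 0.0)
    for rid in atlas.ids_of_class(RegionClass.WHITE_MATTER):
        row[f"{LESION_PREFIX}{atlas.name_of(rid)}__WM"] = lesion_by.get((rid, "WM-lesion"), 0.0)

    deep_ids = atlas.ids_of_class(RegionClass.DEEP_GREY)
    enl_by: dict[int, float] = {rid: 0.0 for rid in deep_ids}
    if truth.enlargement_mask is not None and truth.enlargement_mask.any():
        from scipy import ndimage

        deep_mask = np.isin(atlas.labels, deep_ids)
        _, nearest = ndimage.distance_transform_edt(
            ~deep_mask, sampling=truth.spacing, return_indices=True
        )
        nearest_label = atlas.labels[tuple(nearest)]
        ids, counts = np.unique(nearest_label[truth.enlargement_mask], return_counts=True)
        vox_ml = truth.voxel_volume_mm3 / 1000.0
        for i, c in zip(ids, counts):
            enl_by[int(i)] = enl_by.get(int(i), 0.0) + float(c) * vox_ml
    for rid in deep_ids:
        row[f"{ENLARGEMENT_PREFIX}{atlas.name_of(rid)}"] = enl_by.get(rid, 0.0)
    return row


def _measured_row(
    res: SubjectResult,
    norm: NormativeZScorer,
    ssm: dict[str, VentricleSSM],
    atlas: RegionAtlas,
) -> dict:
    row: dict = {}
    z = norm.transform(res.shape_summary[["region_id", "metric", "value"]])
    for r in z.itertuples():
        row[f"{SHAPE_PREFIX}{atlas.name_of(int(r.region_id))}__{r.metric}"] = float(r.abs_z)

    lesion_by = {
        (int(r.region_id), r.lesion_class): float(r.volume_mL)
        for r in res.lesion_volumes.itertuples()
    }
    for rid in atlas.ids_of_class(RegionClass.CORTICAL) + atlas.ids_of_class(RegionClass.DEEP_GREY):
        row[f"{LESION_PREFIX}{atlas.name_of(rid)}__GM"] = lesion_by.get((rid, "GM-lesion"), 0.0)
    for rid in atlas.ids_of_class(RegionClass.WHITE_MATTER):
        row[f"{LESION_PREFIX}{atlas.name_of(rid)}__WM"] = lesion_by.get((rid, "WM-lesion"), 0.0)

    deep_ids = atlas.ids_of_class(RegionClass.DEEP_GREY)
    enl_by = {rid: 0.0 for rid in deep_ids}
    for side, shape in res.ventricle_shapes.items():
        emap = localize_enlargement(shape, ssm[side].reconstruct(shape), atlas)
        for rid, ml in emap.attributed_ml.items():
            if rid in enl_by:
                enl_by[rid] += ml
    for rid in deep_ids:
        row[f"{ENLARGEMENT_PREFIX}{atlas.name_of(rid)}"] = enl_by[rid]
    return row


def run_cohort_pipeline(
    opts: PipelineOptions,
    generators: dict[str, ScoreGeneratorSpec] | None = None,
    model_seeds: tuple[int, ...] | None = None,
) -> CohortResult:
    """Simulate a cohort and run every stage through the association models.

    ``generators`` overrides the default clinical-score generators;
    ``model_seeds`` is unused here (kept for API symmetry) — the split and
    CV seeds derive from ``opts.seed``.
    """
    subjects = simulate_cohort(
        opts.n_controls,
        opts.n_patients,
        opts.base_config,
        opts.injury_sampler,
        seed=opts.seed,
        jitter=opts.jitter,
    )
    manifest = cohort_manifest(subjects)
    # the atlas frame is shared across subjects (atlas ids are stable)
    atlas = build_anatomy(opts.base_config).atlas

    priors_cache: dict = {}
    control_results: list[SubjectResult] = []
    for sub in subjects[: opts.n_controls]:
        control_results.append(process_subject(sub, opts, priors_cache))
        priors_cache.clear()  # each subject has its own anatomy

    if len(control_results) < 10:
        raise ValueError("pipeline needs >= 10 controls for normative statistics")
    norm = NormativeZScorer().fit(
        [r.shape_summary[["region_id", "metric", "value"]] for r in control_results]
    )
    ssm = {
        side: VentricleSSM(variance_to_retain=opts.ssm_variance).fit(
            [r.ventricle_shapes[side] for r in control_results]
        )
        for side in ("left", "right")
    }

    feature_names = feature_names_for_atlas(atlas)
    rows, truth_rows, profiles = [], [], []
    vox_mm3 = control_results[0].voxel_volume_mm3

    def add_subject(res: SubjectResult) -> None:
        sub = res.subject
        covs = {"age": sub.age, "sex": sub.sex, "sequence": sub.sequence}
        measured = _measured_row(res, norm, ssm, atlas)
        measured_full = {"subject_id": sub.subject_id, "group": sub.group}
        measured_full.update({k: measured.get(k, 0.0) for k in feature_names})
        measured_full.update(covs)
        rows.append(measured_full)
        truth_full = {"subject_id": sub.subject_id, "group": sub.group}
        truth_full.update({k: res.truth_row.get(k, 0.0) for k in feature_names})
        truth_full.update(covs)
        truth_rows.append(truth_full)
        profiles.append(classify_injury(pd.Series(measured), voxel_volume_mm3=vox_mm3))

    for res in control_results:
        add_subject(res)
    del control_results  # volumes already released; free summaries as we go

    for sub in subjects[opts.n_controls :]:
        add_subject(process_subject(sub, opts, priors_cache))
        priors_cache.clear()

    biomarkers = pd.DataFrame(rows).set_index("subject_id")
    truth_biomarkers = pd.DataFrame(truth_rows).set_index("subject_id")

    prevalence = cohort_prevalence(profiles)
    prevalence_patients = cohort_prevalence(profiles[opts.n_controls :]) if opts.n_patients else None

    if generators is None:
        generators = default_score_generators(
            truth_biomarkers,
            target_r2=opts.score_target_r2,
            n_features=opts.score_features,
            seed=opts.seed + 1,
        )
    scores = simulate_clinical_scores(truth_biomarkers, generators)

    if opts.fit_models:
        models, evaluations, comparisons = fit_association_models(
            biomarkers, scores, feature_names, opts
        )
    else:
        models, evaluations, comparisons = {}, {}, {}

    return CohortResult(
        manifest=manifest,
        biomarkers=biomarkers,
        truth_biomarkers=truth_biomarkers,
        scores=scores,
        prevalence=prevalence,
        prevalence_patients=prevalence_patients,
        models=models,
        evaluations=evaluations,
        comparisons=comparisons,
        normative=norm,
        ssm=ssm,
        bonferroni=assoc.bonferroni_threshold(0.05, len(scores.columns)),
    )


def fit_association_models(
    biomarkers: pd.DataFrame,
    scores: pd.DataFrame,
    feature_names: list[str],
    opts: PipelineOptions,
    split_seed: int | None = None,
) -> tuple[dict, dict, dict]:
    """Per-score constrained-LASSO selection, OLS refit and test evaluation."""
    table = assoc.encode_covariates(biomarkers.join(scores))
    covariates = [c for c in assoc.COVARIATE_COLS if c in table.columns]
    threshold = assoc.bonferroni_threshold(0.05, len(scores.columns))
    seed = opts.seed if split_seed is None else split_seed

    models, evaluations, comparisons = {}, {}, {}
    for outcome in scores.columns:
        train, test = assoc.split_data(
            table, outcome, fraction=opts.train_fraction, seed=seed
        )
        cols = feature_names + covariates
        pen = np.array([c in feature_names for c in cols])
        X = train[cols].to_numpy(dtype=float)
        y = train[outcome].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = assoc.NegativeLassoCV(
                penalized=pen, cv=opts.cv_folds, n_lambdas=opts.cv_lambdas, seed=seed
            ).fit(X, y)
        retained = [c for c, b, p in zip(cols, cv.coef_, pen) if p and b != 0.0]
        model = assoc.refit_ols(train, outcome, retained, covariates, lambda_=cv.lambda_)
        model.lasso_coef = pd.Series(cv.coef_[pen], index=np.array(cols)[pen])
        models[outcome] = model
        evaluations[outcome] = assoc.evaluate_test(model, test, alpha_threshold=threshold)
        comparisons[outcome] = {
            fam: assoc.compare_models_anova(model, fam, train)
            for fam in ("cortical-only", "lesion-only")
        }
    return models, evaluations, comparisons
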