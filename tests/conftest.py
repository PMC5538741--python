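"""Shared fixtures.

Heavy phantom cohorts are session-scoped and shared across test modules so
the suite stays within a sensible runtime: ``control_cohort`` (20 jittered
control phantoms, segmented with shape summaries and ventricle SDFs) backs
the normative-statistics, shape-model and acceptance tests, and
``full_cohort`` (44 controls + 95 patients) backs the end-to-end
structure-function recovery checks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cpinjury.cortical import compute_shape_maps, summarize_regions
from cpinjury.phantom import (
    AcquisitionSpec,
    PhantomConfig,
    SulciSpec,
    build_anatomy,
    inject_injuries,
    simulate_cohort,
    simulate_mri,
)
from cpinjury.pipeline import PipelineOptions, run_cohort_pipeline
from cpinjury.preprocess import BrainMask, normalize_intensity, strip_skull
from cpinjury.segmentation import EMMRFSegmenter, make_tissue_priors
from cpinjury.ventricles import extract_ventricle_shape

COHORT_NOISE = (5.0, 5.0)


def small_grid_config() -> PhantomConfig:
    """A 48^3 configuration for fast smoke/determinism runs."""
    return PhantomConfig(
        grid_shape=(48, 48, 48),
        brain_radii_mm=(14.0, 17.0, 14.0),
        gm_thickness_mm=3.0,
        csf_thickness_mm=2.0,
        skull_thickness_mm=2.0,
        sulci=SulciSpec(amplitude_mm=1.5, wavelength_mm=12.0),
        ventricle_radii_mm=((3.5, 6.0, 3.5), (3.5, 6.0, 3.5)),
    )


def segment_subject(truth, acq_seed: int, beta: float = 0.5, base_anatomy=None):
    """Minimal preprocess + EM segmentation used by unit-level fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t1, t2 = simulate_mri(truth, AcquisitionSpec(noise_sigma=COHORT_NOISE, seed=acq_seed))
        mask = strip_skull(t1)
        t1n = normalize_intensity(t1, mask)
        t2n = normalize_intensity(t2, mask)
        priors = make_tissue_priors(base_anatomy if base_anatomy is not None else truth)
        model = EMMRFSegmenter(beta=beta).fit(t1n, t2n, mask, priors)
    return model, mask


@pytest.fixture(scope="session")
def cohort_config() -> PhantomConfig:
    return PhantomConfig.cohort_default()


@pytest.fixture(scope="session")
def control_cohort(cohort_config):
    """20 anatomically jittered control phantoms, fully segmented.

    Returns a list of dicts with the subject, its anatomy, the fitted
    segmenter, brain mask, regional shape summary and per-side ventricle
    SDFs.
    """
    subjects = simulate_cohort(20, 0, cohort_config, seed=101)
    out = []
    for sub in subjects:
        anatomy = build_anatomy(sub.config)
        model, mask = segment_subject(anatomy, sub.acq_seed, base_anatomy=anatomy)
        maps = compute_shape_maps(model.result_, mask)
        summary = summarize_regions(maps, anatomy.atlas)
        shapes = {
            side: extract_ventricle_shape(model.result_, anatomy.atlas, side,
                                          subject_id=sub.subject_id)
            for side in ("left", "right")
        }
        out.append({
            "subject": sub,
            "anatomy": anatomy,
            "model": model,
            "mask": mask,
            "summary": summary,
            "shapes": shapes,
        })
    return out


@pytest.fixture(scope="session")
def full_cohort():
    """The cohort-scale end-to-end pipeline run (44 controls, 95 patients)."""
    opts = PipelineOptions(
        n_controls=44,
        n_patients=95,
        seed=1,
        fit_models=False,  # association models are fitted per-test (multiple seeds)
        acquisition=AcquisitionSpec(noise_sigma=COHORT_NOISE, bias_amplitude=0.2),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_cohort_pipeline(opts)
    return opts, result
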