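"""Ventricle statistical shape model: extraction, PCA, reconstruction and
localized enlargement."""

import numpy as np
import pytest

from cpinjury.phantom import (
    EnlargementSpec,
    InjurySpec,
    inject_injuries,
)
from cpinjury.ventricles import (
    EnlargementMap,
    ExtractionError,
    VentricleShape,
    VentricleSSM,
    build_ssm,
    extract_ventricle_shape,
    localize_enlargement,
    reconstruct_healthy,
)
from cpinjury.ventricles import _signed_distance
from cpinjury.volume import Label

from tests.conftest import segment_subject


def ellipsoid_sdf(radii, n=32, centre=None, band=4.0):
    ax = np.arange(n) - (n - 1) / 2
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    if centre is not None:
        x, y, z = x - centre[0], y - centre[1], z - centre[2]
    mask = (x / radii[0]) ** 2 + (y / radii[1]) ** 2 + (z / radii[2]) ** 2 <= 1
    return _signed_distance(mask, (1, 1, 1), band_mm=band)


def shapes_from_radii(radii_list, side="left"):
    return [
        VentricleShape(sdf=ellipsoid_sdf(r), side=side, subject_id=str(i))
        for i, r in enumerate(radii_list)
    ]


class TestSSMCore:
    def test_two_shapes_give_one_mode_and_midpoint_mean(self):
        shapes = shapes_from_radii([(4, 6, 4), (5, 7, 5)])
        model = VentricleSSM(min_controls=2).fit(shapes)
        assert model.n_modes_ == 1
        nontrivial = model.all_eigenvalues_ > 1e-12 * model.all_eigenvalues_[0]
        assert nontrivial.sum() == 1
        midpoint = 0.5 * (shapes[0].sdf + shapes[1].sdf)
        assert np.allclose(model.mean_.reshape(midpoint.shape), midpoint, atol=1e-6)

    def test_identical_shapes_collapse_to_mean(self):
        shapes = shapes_from_radii([(4, 6, 4)] * 12)
        model = VentricleSSM().fit(shapes)
        assert model.n_modes_ == 0
        rec = model.reconstruct(shapes[0])
        assert np.allclose(rec.sdf, shapes[0].sdf, atol=1e-6)

    def test_two_generative_modes_recovered(self):
        """20 shapes driven by 2 shape parameters: first 2 PCA modes carry
        >= 90% of the variance (smooth analytic distance fields, so the
        generative parameters enter the representation continuously)."""
        rng = np.random.default_rng(0)
        n = 32
        ax = np.arange(n) - (n - 1) / 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")

        def analytic_sdf(a, b, c):
            rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2) - 1.0
            return np.clip(rho * (a * b * c) ** (1 / 3), -4, 4).astype(np.float32)

        shapes = [
            VentricleShape(
                sdf=analytic_sdf(4 + rng.normal(0, 0.4), 6 + rng.normal(0, 0.5), 4),
                side="left",
            )
            for _ in range(20)
        ]
        model = VentricleSSM(variance_to_retain=0.999).fit(shapes)
        frac2 = model.all_eigenvalues_[:2].sum() / model.all_eigenvalues_.sum()
        assert frac2 >= 0.90

    def test_eigenvector_sign_convention(self):
        shapes = shapes_from_radii([(4, 6, 4), (5, 7, 5), (4.5, 6.5, 4.5)])
        model = VentricleSSM(min_controls=3).fit(shapes)
        for comp in model.components_:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_components_orthonormal(self):
        rng = np.random.default_rng(1)
        shapes = shapes_from_radii([(4 + rng.normal(0, 0.5), 6 + rng.normal(0, 0.5), 4)
                                    for _ in range(15)])
        model = VentricleSSM().fit(shapes)
        gram = model.components_ @ model.components_.T
        assert np.allclose(gram, np.eye(model.n_modes_), atol=1e-6)

    def test_too_few_controls_raises(self):
        with pytest.raises(ValueError):
            VentricleSSM().fit(shapes_from_radii([(4, 6, 4)] * 5))

    def test_mixed_sides_raise(self):
        shapes = shapes_from_radii([(4, 6, 4)] * 6) + shapes_from_radii(
            [(4, 6, 4)] * 6, side="right"
        )
        with pytest.raises(ValueError):
            VentricleSSM(min_controls=2).fit(shapes)


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(2)
    radii = [(4 + rng.normal(0, 0.5), 6 + rng.normal(0, 0.7), 4 + rng.normal(0, 0.5))
             for _ in range(20)]
    return VentricleSSM().fit(shapes_from_radii(radii))


class TestReconstruction:

    def test_mean_shape_reconstructs_to_itself(self, model):
        mean_shape = VentricleShape(
            sdf=model.mean_.reshape(model.grid_shape_).astype(np.float32), side="left"
        )
        assert np.allclose(model.transform(mean_shape), 0.0, atol=1e-4)
        rec = model.reconstruct(mean_shape)
        assert np.allclose(rec.sdf, mean_shape.sdf, atol=1e-4)

    def test_training_shape_error_bounded_by_subspace_distance(self, model):
        shape = shapes_from_radii([(4.3, 6.1, 4.2)])[0]
        centred = shape.sdf.ravel() - model.mean_
        proj = model.components_.T @ (model.components_ @ centred)
        subspace_err = np.abs(centred - proj).mean()
        rec = reconstruct_healthy(shape, model)
        rec_err = np.abs(rec.sdf.ravel() - shape.sdf.ravel()).mean()
        assert rec_err <= subspace_err + 1e-9

    def test_far_shape_clamps_exactly(self, model):
        far = VentricleShape(sdf=ellipsoid_sdf((8, 12, 8)), side="left")
        raw = model.components_ @ (far.sdf.ravel() - model.mean_)
        clamped = model.transform(far)
        bound = model.clamp_sd * np.sqrt(model.eigenvalues_)
        exceeded = np.abs(raw) > bound
        assert exceeded.any()
        assert np.allclose(np.abs(clamped[exceeded]), bound[exceeded])

    def test_grid_mismatch_raises(self, model):
        with pytest.raises(ValueError):
            model.transform(VentricleShape(sdf=ellipsoid_sdf((4, 6, 4), n=24), side="left"))


class TestLocalization:
    def test_attribution_partitions_total(self, control_cohort):
        """Per-anatomy attributed volumes sum exactly to the total."""
        model = build_ssm([c["shapes"]["left"] for c in control_cohort])
        patient = control_cohort[0]
        injured = inject_injuries(
            patient["anatomy"],
            InjurySpec(ventricle_enlargement=[EnlargementSpec("left", 2.0)]),
        )
        seg_model, _ = segment_subject(injured, acq_seed=7, base_anatomy=patient["anatomy"])
        shape = extract_ventricle_shape(seg_model.result_, injured.atlas, "left")
        emap = localize_enlargement(shape, model.reconstruct(shape), injured.atlas)
        assert sum(emap.attributed_ml.values()) == pytest.approx(emap.total_ml, abs=1e-12)
        assert all(v >= 0 for v in emap.attributed_ml.values())

    def test_control_within_envelope(self, control_cohort):
        model = build_ssm([c["shapes"]["left"] for c in control_cohort[1:]])
        c0 = control_cohort[0]
        emap = localize_enlargement(
            c0["shapes"]["left"], model.reconstruct(c0["shapes"]["left"]), c0["anatomy"].atlas
        )
        assert emap.total_ml <= 0.2

    def test_leave_one_out_residual_small(self, control_cohort):
        """LOO reconstruction residual volume < 5% of the mean volume."""
        shapes = [c["shapes"]["left"] for c in control_cohort]
        residuals = []
        for i, c in enumerate(control_cohort):
            model = build_ssm([s for j, s in enumerate(shapes) if j != i])
            emap = localize_enlargement(
                shapes[i], model.reconstruct(shapes[i]), c["anatomy"].atlas
            )
            residuals.append(emap.total_ml)
        mean_volume = np.mean([s.volume_ml for s in shapes])
        assert np.mean(residuals) < 0.05 * mean_volume

    def test_injected_enlargement_detected_and_attributed(self, control_cohort):
        """A +2 mL directional lobe is detected within +-30% and mostly
        attributed to the deep-GM sector it points at."""
        model = build_ssm([c["shapes"]["left"] for c in control_cohort])
        base = control_cohort[3]["anatomy"]
        direction = (0.0, np.cos(np.pi / 4), np.sin(np.pi / 4))  # sector centre
        injured = inject_injuries(
            base,
            InjurySpec(ventricle_enlargement=[
                EnlargementSpec("left", 2.0, direction=direction, cone_cos=0.45)
            ]),
        )
        seg_model, _ = segment_subject(injured, acq_seed=77, base_anatomy=base)
        shape = extract_ventricle_shape(seg_model.result_, injured.atlas, "left")
        emap = localize_enlargement(shape, model.reconstruct(shape), injured.atlas)
        assert emap.total_ml == pytest.approx(2.0, rel=0.30)
        by_name = {
            injured.atlas.name_of(k): v for k, v in emap.attributed_ml.items()
        }
        target = by_name.get("left_putamen", 0.0)
        assert target >= 0.6 * emap.total_ml, by_name

    def test_monotone_in_injected_volume(self, control_cohort):
        model = build_ssm([c["shapes"]["left"] for c in control_cohort])
        base = control_cohort[5]["anatomy"]
        detected = []
        for ml in (0.0, 1.0, 2.0, 4.0):
            injured = inject_injuries(
                base, InjurySpec(ventricle_enlargement=[EnlargementSpec("left", ml)])
            )
            seg_model, _ = segment_subject(injured, acq_seed=78, base_anatomy=base)
            shape = extract_ventricle_shape(seg_model.result_, injured.atlas, "left")
            emap = localize_enlargement(shape, model.reconstruct(shape), injured.atlas)
            detected.append(emap.total_ml)
        assert all(b >= a - 0.05 for a, b in zip(detected, detected[1:])), detected


class TestExtraction:
    def test_control_volume_close_to_truth(self, control_cohort):
        c = control_cohort[0]
        labels = c["anatomy"].labels
        half = np.arange(labels.shape[0])[:, None, None] < labels.shape[0] / 2
        true_vol = (
            ((labels == Label.VENTRICLE) & half).sum()
            * c["anatomy"].voxel_volume_mm3 / 1000.0
        )
        assert c["shapes"]["left"].volume_ml == pytest.approx(true_vol, rel=0.10)

    def test_enlarged_exceeds_matched_control(self, control_cohort):
        c = control_cohort[2]
        injured = inject_injuries(
            c["anatomy"], InjurySpec(ventricle_enlargement=[EnlargementSpec("left", 2.0)])
        )
        seg_model, _ = segment_subject(injured, acq_seed=79, base_anatomy=c["anatomy"])
        shape = extract_ventricle_shape(seg_model.result_, injured.atlas, "left")
        excess = shape.volume_ml - c["shapes"]["left"].volume_ml
        assert excess == pytest.approx(2.0, rel=0.20)

    def test_csf_free_segmentation_raises(self, control_cohort):
        c = control_cohort[0]
        seg = c["model"].result_
        import copy

        broken = copy.deepcopy(seg)
        k_csf = broken.class_names.index("CSF")
        k_wm = broken.class_names.index("WM")
        broken.posteriors[k_wm] += broken.posteriors[k_csf]
        broken.posteriors[k_csf][:] = 0.0
        with pytest.raises(ExtractionError):
            extract_ventricle_shape(broken, c["anatomy"].atlas, "left")
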