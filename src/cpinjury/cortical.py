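"""Cortical shape morphometry: thickness, curvature and sulcal depth.

Three voxel-based shape measures are computed from the grey-matter
segmentation:

* **thickness** (mm): for every GM voxel, the sum of the Euclidean
  distances to the white-matter interface and to the pial interface
  (symmetric nearest-boundary distances; a fast surrogate for
  streamline-based thickness that is accurate on ribbon geometry);
* **curvature** (mm^-1): the divergence of the unit normal of the signed
  distance embedding of the pial surface, ``div(grad phi / |grad phi|)``,
  i.e. the sum of principal curvatures (2/R on a sphere of radius R); a
  Gaussian-curvature variant (mm^-2) is available behind a switch;
* **sulcal depth** (mm): the distance from the morphological closing hull
  of the brain (ball radius 15 mm) down to each pial-surface voxel.

Regional summaries are means over cortical-surface voxels per atlas
region; patient values are expressed as absolute z-scores against a
normative control cohort via :class:`NormativeZScorer`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import BrainMask
from .segmentation import SegmentationResult
from .volume import RegionAtlas, RegionClass

__all__ = [
    "ShapeMaps",
    "compute_shape_maps",
    "summarize_regions",
    "NormativeZScorer",
    "build_normative_stats",
    "zscore_regions",
    "SHAPE_METRICS",
    "DegenerateNormativeError",
]

SHAPE_METRICS = ("thickness", "curvature", "sulcal_depth")


class DegenerateNormativeError(ValueError):
    """Normative statistics unusable (too few controls or zero variance)."""


@dataclass
class ShapeMaps:
    """Thickness / curvature / sulcal-depth maps on cortical voxels.

    ``surface`` flags the pial-surface GM voxels on which curvature and
    sulcal depth are defined and over which regions are summarised.
    """

    thickness: np.ndarray
    curvature: np.ndarray
    sulcal_depth: np.ndarray
    gm_mask: np.ndarray
    surface: np.ndarray
    spacing: tuple[float, float, float]

    def metric(self, name: str) -> np.ndarray:
        return {"thickness": self.thickness, "curvature": self.curvature,
                "sulcal_depth": self.sulcal_depth}[name]


def _ball_morphology(mask: np.ndarray, radius_mm: float, spacing, op: str) -> np.ndarray:
    """Ball dilation/erosion via distance transforms (fast for large radii)."""
    if op == "dilate":
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
        return dist <= radius_mm
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    return dist > radius_mm


def closing_hull(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Morphological closing with a ball of the given radius."""
    dilated = _ball_morphology(mask, radius_mm, spacing, "dilate")
    dist_in = ndimage.distance_transform_edt(dilated, sampling=spacing)
    return dist_in > radius_mm - 1e-9


def compute_shape_maps(
    seg: SegmentationResult,
    mask: BrainMask,
    hull_radius_mm: float = 15.0,
    curvature_kind: str = "mean",
    smooth_sigma_mm: float = 1.0,
) -> ShapeMaps:
    """Compute the three cortical shape maps from a segmentation.

    ``curvature_kind`` selects the reported curvature: ``"mean"`` is the
    divergence of the pial surface normal (mm^-1), ``"gaussian"`` the
    product of principal curvatures (mm^-2).
    """
    gm = seg.class_mask("GM") | seg.class_mask("GM-lesion")
    if not gm.any():
        raise ValueError("segmentation contains no grey matter")
    wm = seg.class_mask("WM") | seg.class_mask("WM-lesion")
    spacing = seg.spacing

    # brain interior bounded by the pial surface (GM + everything inside it)
    interior = gm | wm
    interior = ndimage.binary_fill_holes(interior)

    # thickness: distance to the WM interface plus distance to the pial
    # interface; subtracting one voxel removes the centre-to-centre offset
    d_wm = ndimage.distance_transform_edt(~wm, sampling=spacing)
    d_pial = ndimage.distance_transform_edt(interior, sampling=spacing)
    mean_sp = float(np.mean(spacing))
    thickness = np.where(gm, np.maximum(d_wm + d_pial - mean_sp, mean_sp * 0.5), 0.0)

    # signed distance embedding of the pial surface (negative inside)
    phi = np.where(
        interior,
        -ndimage.distance_transform_edt(interior, sampling=spacing),
        ndimage.distance_transform_edt(~interior, sampling=spacing),
    )
    sigma_vox = smooth_sigma_mm / np.asarray(spacing)
    phi_s = ndimage.gaussian_filter(phi, sigma_vox)
    gx, gy, gz = np.gradient(phi_s, *spacing)
    gmag = np.sqrt(gx * gx + gy * gy + gz * gz) + 1e-9
    if curvature_kind == "mean":
        curv = (
            np.gradient(gx / gmag, spacing[0], axis=0)
            + np.gradient(gy / gmag, spacing[1], axis=1)
            + np.gradient(gz / gmag, spacing[2], axis=2)
        )
    elif curvature_kind == "gaussian":
        curv = _gaussian_curvature(phi_s, spacing)
    else:
        raise ValueError(f"unknown curvature kind {curvature_kind!r}")

    # pial-surface voxels: GM voxels touching the exterior
    exterior = ~interior
    surface = gm & ndimage.binary_dilation(exterior)

    # hull of the pial-bounded interior: sulcal depth is measured from the
    # outer cortical hull, not from the CSF/skull boundary
    hull = closing_hull(interior, hull_radius_mm, spacing)
    # erode one voxel so surface voxels in contact with the hull read ~0
    # (the closing leaves a one-voxel rind above the pial surface)
    hull = ndimage.binary_erosion(hull)
    depth = ndimage.distance_transform_edt(hull, sampling=spacing)
    sulcal_depth = np.where(surface, depth, 0.0)

    return ShapeMaps(
        thickness=thickness.astype(np.float32),
        curvature=np.where(surface, curv, 0.0).astype(np.float32),
        sulcal_depth=sulcal_depth.astype(np.float32),
        gm_mask=gm,
        surface=surface,
        spacing=spacing,
    )


def _gaussian_curvature(phi: np.ndarray, spacing) -> np.ndarray:
    """K = (grad phi)^T adj(H) (grad phi) / |grad phi|^4 for a level set."""
    g = np.gradient(phi, *spacing)
    h = [[np.gradient(g[i], spacing[j], axis=j) for j in range(3)] for i in range(3)]
    gx, gy, gz = g
    # adjugate of the Hessian
    a00 = h[1][1] * h[2][2] - h[1][2] * h[2][1]
    a01 = h[0][2] * h[2][1] - h[0][1] * h[2][2]
    a02 = h[0][1] * h[1][2] - h[0][2] * h[1][1]
    a11 = h[0][0] * h[2][2] - h[0][2] * h[2][0]
    a12 = h[0][2] * h[1][0] - h[0][0] * h[1][2]
    a22 = h[0][0] * h[1][1] - h[0][1] * h[1][0]
    num = (
        gx * (a00 * gx + a01 * gy + a02 * gz)
        + gy * (a01 * gx + a11 * gy + a12 * gz)
        + gz * (a02 * gx + a12 * gy + a22 * gz)
    )
    gmag2 = gx * gx + gy * gy + gz * gz + 1e-9
    return num / gmag2**2


def summarize_regions(
    maps: ShapeMaps, atlas: RegionAtlas, min_surface_voxels: int = 20
) -> pd.DataFrame:
    """Mean of each shape map over the surface voxels of each cortical region.

    Returns a frame with columns region_id, metric, value, n_voxels and an
    ``unreliable`` flag for regions with fewer than ``min_surface_voxels``
    surface voxels (their value is still reported).
    """
    cortical = atlas.ids_of_class(RegionClass.CORTICAL)
    if not cortical:
        raise ValueError("atlas has no cortical regions")
    rows = []
    for rid in cortical:
        region_surf = atlas.mask(rid) & maps.surface
        n = int(region_surf.sum())
        # thickness is defined on the full ribbon, the others on the surface
        region_gm = atlas.mask(rid) & maps.gm_mask
        for metric in SHAPE_METRICS:
            support = region_gm if metric == "thickness" else region_surf
            value = float(maps.metric(metric)[support].mean()) if support.any() else np.nan
            rows.append((rid, metric, value, n, n < min_surface_voxels))
    return pd.DataFrame(
        rows, columns=["region_id", "metric", "value", "n_surface_voxels", "unreliable"]
    )


class NormativeZScorer(BaseEstimator, TransformerMixin):
    """Absolute z-scores of regional shape measures against controls.

    ``fit`` consumes a list of per-control regional summary frames (as
    returned by :func:`summarize_regions`) and stores the per (region,
    metric) control mean and sd (ddof=1).  ``transform`` maps a patient
    summary to ``|z| = |x - mu| / sd``.

    Parameters
    ----------
    min_controls : minimum normative cohort size (10 by default).
    """

    def __init__(self, min_controls: int = 10):
        self.min_controls = min_controls

    def fit(self, summaries: list[pd.DataFrame], y=None) -> "NormativeZScorer":
        if len(summaries) < self.min_controls:
            raise DegenerateNormativeError(
                f"need >= {self.min_controls} controls, got {len(summaries)}"
            )
        stacked = pd.concat(
            [s.assign(control=i) for i, s in enumerate(summaries)], ignore_index=True
        )
        grouped = stacked.groupby(["region_id", "metric"])["value"]
        stats = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
        self.stats_ = stats
        self.n_controls_ = len(summaries)
        return self

    def transform(self, summary: pd.DataFrame) -> pd.DataFrame:
        """Absolute z-scores for one subject's regional summary."""
        merged = summary.merge(self.stats_, on=["region_id", "metric"], how="left", validate="one_to_one")
        if merged["mean"].isna().any():
            missing = merged.loc[merged["mean"].isna(), ["region_id", "metric"]]
            raise KeyError(f"no normative entry for {missing.to_records(index=False).tolist()}")
        degenerate = merged["sd"] <= 0
        if degenerate.any():
            bad = merged.loc[degenerate, ["region_id", "metric"]]
            raise DegenerateNormativeError(
                f"zero control variance for {bad.to_records(index=False).tolist()}"
            )
        merged["abs_z"] = (merged["value"] - merged["mean"]).abs() / merged["sd"]
        return merged[["region_id", "metric", "value", "abs_z"]]


def build_normative_stats(control_summaries: list[pd.DataFrame], min_controls: int = 10) -> NormativeZScorer:
    """Fit a :class:`NormativeZScorer` on control regional summaries."""
    return NormativeZScorer(min_controls=min_controls).fit(control_summaries)


def zscore_regions(patient_summary: pd.DataFrame, norm: NormativeZScorer) -> pd.DataFrame:
    """Absolute regional z-scores for one patient (thin wrapper)."""
    return norm.transform(patient_summary)
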