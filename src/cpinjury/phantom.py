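"""Synthetic brain phantoms with known ground truth.

The anatomy is a sulcated ellipsoid shell model: concentric background /
skull / intradural CSF / cortical grey-matter ribbon / white matter, with
two ellipsoidal lateral ventricles.  It is deliberately schematic — the
downstream methods need tissue interfaces, regional labels and injuries
with exactly known volumes, not anatomical realism.

Three injury aetiologies can be injected with exact ground truth:

* focal WM/GM lesions (spheres with a per-modality intensity contrast),
* localized ventricular enlargement (directional dilation into
  periventricular white matter until a target added volume is reached),
* regional cortical thinning (the GM ribbon rescaled in selected atlas
  sectors).

MR acquisition is emulated as per-tissue mean intensities modulated by a
smooth polynomial bias field and corrupted by Rician noise
``sqrt((s+n1)^2 + n2^2)`` with ``n1, n2 ~ N(0, sigma)``.

Clinical scores are generated as sparse non-positive linear functions of
the true injury biomarkers plus age/sex/sequence covariate effects and
Gaussian noise, mirroring the sign convention of the downstream
sign-constrained regression.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import ImageVolume, Label, RegionAtlas, RegionClass

__all__ = [
    "PhantomConfig",
    "SulciSpec",
    "LesionSpec",
    "EnlargementSpec",
    "ThinningSpec",
    "InjurySpec",
    "AcquisitionSpec",
    "GroundTruth",
    "ScoreGeneratorSpec",
    "InjurySampler",
    "AnatomyJitter",
    "Subject",
    "build_anatomy",
    "inject_injuries",
    "simulate_mri",
    "simulate_cohort",
    "realize_subject",
    "simulate_clinical_scores",
    "default_score_generators",
    "SCORE_NAMES",
    "PlacementError",
    "SizingError",
]

SCORE_NAMES = ("AHA", "BRIEF", "SDQ", "TVPS", "WR", "VOC")

DEEP_GM_NAMES = ("caudate", "thalamus", "putamen", "pallidum")


class SizingError(ValueError):
    """Grid too small for the requested anatomy."""


class PlacementError(ValueError):
    """Injury placed outside its target tissue."""


@dataclass
class SulciSpec:
    """Periodic indentation of the pial surface.

    ``amplitude_mm`` is the trough depth; ``wavelength_mm`` the arc length
    of one full fold at the mean equatorial radius.  The profile is a
    clipped cosine (flat-bottomed troughs separated by narrow ridges), so
    the mean indentation is a substantial fraction of the amplitude.
    ``sectors`` restricts the folding to the given cortical sector indices
    (0..7); None folds the whole surface.  ``phase`` rotates the fold
    pattern (radians).
    """

    amplitude_mm: float = 2.0
    wavelength_mm: float = 15.0
    sectors: tuple[int, ...] | None = None
    phase: float = 0.0


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radii_mm: tuple[float, float, float] = (30.0, 36.0, 30.0)
    gm_thickness_mm: float = 3.0
    sulci: SulciSpec = field(default_factory=SulciSpec)
    csf_thickness_mm: float = 2.0
    skull_thickness_mm: float = 3.0
    ventricle_radii_mm: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (6.0, 10.0, 6.0),
        (6.0, 10.0, 6.0),
    )
    ventricle_offset_frac: float = 0.38  # lateral offset of each ventricle, fraction of x semi-axis
    seed: int = 0

    @classmethod
    def cohort_default(cls) -> "PhantomConfig":
        """64^3 configuration used for cohort-scale simulation runs."""
        return cls(
            grid_shape=(64, 64, 64),
            brain_radii_mm=(20.0, 24.0, 20.0),
            gm_thickness_mm=3.0,
            csf_thickness_mm=2.0,
            skull_thickness_mm=2.0,
            ventricle_radii_mm=((5.5, 9.5, 5.5), (5.5, 9.5, 5.5)),
        )

    def __post_init__(self) -> None:
        if self.gm_thickness_mm <= 0:
            raise ValueError("gm_thickness_mm must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        # brain + CSF + skull must fit with a >=2-voxel margin on every axis
        for ax in range(3):
            half_extent = (
                self.brain_radii_mm[ax] + self.csf_thickness_mm + self.skull_thickness_mm
            )
            half_grid = self.grid_shape[ax] * self.spacing_mm[ax] / 2.0
            if half_extent + 2 * self.spacing_mm[ax] > half_grid:
                raise SizingError(
                    f"axis {ax}: anatomy half-extent {half_extent:.1f} mm + 2-voxel margin "
                    f"exceeds half grid {half_grid:.1f} mm"
                )


@dataclass
class LesionSpec:
    """A spherical focal lesion. ``center_mm`` is relative to the brain centre."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    tissue: str  # "WM" or "GM"
    contrast: tuple[float, float] = (0.7, 1.7)  # multiplicative (T1, T2) shift

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.tissue not in ("WM", "GM"):
            raise ValueError(f"lesion tissue must be WM or GM, got {self.tissue!r}")


@dataclass
class EnlargementSpec:
    side: str  # "left" or "right"
    added_volume_ml: float
    direction: tuple[float, float, float] | None = (0.0, 1.0, 0.0)
    cone_cos: float = 0.2  # lobe half-width: growth restricted to cos(angle) >= this

    def __post_init__(self) -> None:
        if self.added_volume_ml < 0:
            raise ValueError("added volume must be >= 0")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")


@dataclass
class ThinningSpec:
    region_id: int
    thickness_scale: float

    def __post_init__(self) -> None:
        if not (0 < self.thickness_scale <= 2):
            raise ValueError("thickness_scale must be in (0, 2]")


@dataclass
class InjurySpec:
    lesions: list[LesionSpec] = field(default_factory=list)
    ventricle_enlargement: list[EnlargementSpec] = field(default_factory=list)
    cortical_thinning: list[ThinningSpec] = field(default_factory=list)
    seed: int = 0

    @property
    def empty(self) -> bool:
        return not (self.lesions or self.ventricle_enlargement or self.cortical_thinning)


def _default_means_t1() -> dict[int, float]:
    return {
        int(Label.BACKGROUND): 5.0,
        int(Label.SKULL): 220.0,
        int(Label.CSF): 40.0,
        int(Label.GM): 120.0,
        int(Label.WM): 160.0,
        int(Label.VENTRICLE): 40.0,
        int(Label.WM_LESION): 160.0,  # parent mean; per-lesion contrast multiplies it
        int(Label.GM_LESION): 120.0,
    }


def _default_means_t2() -> dict[int, float]:
    return {
        int(Label.BACKGROUND): 5.0,
        int(Label.SKULL): 60.0,
        int(Label.CSF): 200.0,
        int(Label.GM): 110.0,
        int(Label.WM): 80.0,
        int(Label.VENTRICLE): 200.0,
        int(Label.WM_LESION): 80.0,
        int(Label.GM_LESION): 110.0,
    }


@dataclass
class AcquisitionSpec:
    """Per-tissue MR intensity model plus bias-field and noise parameters."""

    tissue_means_t1: dict[int, float] = field(default_factory=_default_means_t1)
    tissue_means_t2: dict[int, float] = field(default_factory=_default_means_t2)
    tissue_sds: dict[int, float] = field(default_factory=dict)  # within-tissue texture, default 0
    bias_order: int = 2
    bias_amplitude: float = 0.0  # fraction of the local mean, in [0, 0.5]
    noise_sigma: tuple[float, float] = (5.0, 5.0)  # Rician sigma per modality (T1, T2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.bias_amplitude <= 0.5):
            raise ValueError("bias amplitude must lie in [0, 0.5]")
        if any(s < 0 for s in self.noise_sigma):
            raise ValueError("noise sigma must be >= 0")
        for d in (self.tissue_means_t1, self.tissue_means_t2):
            if any(v <= 0 for v in d.values()):
                raise ValueError("tissue intensities must be positive")


@dataclass
class GroundTruth:
    """Phantom ground truth: labels, atlas and exact injury volumes."""

    labels: np.ndarray
    atlas: RegionAtlas
    spacing: tuple[float, float, float]
    config: PhantomConfig
    contrast_t1: np.ndarray
    contrast_t2: np.ndarray
    true_lesion_volumes: pd.DataFrame  # region_id, lesion_class, volume_mL
    true_enlargement_ml: dict[str, float]
    true_thickness_mm: dict[int, float]
    # geometry caches used by injury injection
    radial_mm: np.ndarray = None
    pial_offset_mm: np.ndarray = None
    ventricle_centers_mm: dict[str, np.ndarray] = field(default_factory=dict)
    enlargement_mask: np.ndarray = None  # voxels added by ventricle enlargement

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def tissue_mask(self, *labels: Label) -> np.ndarray:
        return np.isin(self.labels, [int(l) for l in labels])

    @property
    def brain_mask(self) -> np.ndarray:
        """Brain tissues plus intradural CSF (everything inside the skull)."""
        return self.tissue_mask(
            Label.CSF, Label.GM, Label.WM, Label.VENTRICLE, Label.WM_LESION, Label.GM_LESION
        )

    def total_lesion_ml(self) -> float:
        n = int(self.tissue_mask(Label.WM_LESION, Label.GM_LESION).sum())
        return n * self.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# anatomy construction
# ---------------------------------------------------------------------------


def _coordinate_grid(config: PhantomConfig) -> tuple[np.ndarray, ...]:
    """Voxel coordinates in mm, relative to the grid centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(config.grid_shape, config.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _cortical_sector(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Eight angular sectors: 4 azimuth quadrants x inferior/superior."""
    theta = np.arctan2(y, x)
    itheta = np.clip(((theta + np.pi) / (np.pi / 2)).astype(int), 0, 3)
    return np.where(z >= 0, 4, 0) + itheta


def _radial_geometry(config: PhantomConfig):
    """Signed radial distance (mm) to the unperturbed pial ellipsoid and the
    sulcal pial offset per voxel."""
    x, y, z = _coordinate_grid(config)
    r = np.sqrt(x * x + y * y + z * z)
    a, b, c = config.brain_radii_mm
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = np.sqrt((x / (r * a)) ** 2 + (y / (r * b)) ** 2 + (z / (r * c)) ** 2)
        r_dir = np.where(inv > 0, 1.0 / np.maximum(inv, 1e-12), min(a, b, c))
    radial = r - r_dir

    sul = config.sulci
    pial_offset = np.zeros_like(radial)
    if sul is not None and sul.amplitude_mm > 0:
        # folds are latitude rings: meridian arc length sets the phase, so
        # the fold spacing stays constant over the whole surface (azimuthal
        # folds would degenerate to sub-voxel size near the poles)
        polar = np.arccos(np.clip(z / np.maximum(r, 1e-9), -1, 1))
        r_ref = (a * b * c) ** (1.0 / 3.0)
        phase = 2 * np.pi * polar * r_ref / sul.wavelength_mm + sul.phase
        # clipped cosine: flat troughs of depth A, ridges at the base surface
        profile = np.minimum((1 - np.cos(phase)) / (1 - np.cos(np.pi / 6)), 1.0)
        pert = -sul.amplitude_mm * profile
        if sul.sectors is not None:
            sector = _cortical_sector(x, y, z)
            pert = np.where(np.isin(sector, list(sul.sectors)), pert, 0.0)
        pial_offset = pert
    return (x, y, z), radial.astype(np.float32), pial_offset.astype(np.float32)


def _ventricle_centers(config: PhantomConfig) -> dict[str, np.ndarray]:
    off = config.ventricle_offset_frac * config.brain_radii_mm[0]
    return {"left": np.array([-off, 0.0, 0.0]), "right": np.array([off, 0.0, 0.0])}


def build_anatomy(config: PhantomConfig) -> GroundTruth:
    """Construct the control (injury-free) phantom anatomy and its atlas.

    Deterministic given the config.  Raises :class:`SizingError` if the
    grid cannot hold the requested anatomy with a 2-voxel margin (checked
    at config construction).
    """
    (x, y, z), radial, pial_offset = _radial_geometry(config)
    t = config.gm_thickness_mm
    csf_t = config.csf_thickness_mm
    skull_t = config.skull_thickness_mm

    labels = np.zeros(config.grid_shape, dtype=np.uint8)
    labels[radial < csf_t + skull_t] = Label.SKULL
    labels[radial < csf_t] = Label.CSF
    labels[radial < pial_offset] = Label.GM
    labels[radial < pial_offset - t] = Label.WM

    centers = _ventricle_centers(config)
    for side, radii in zip(("left", "right"), config.ventricle_radii_mm):
        c = centers[side]
        e = (
            ((x - c[0]) / radii[0]) ** 2
            + ((y - c[1]) / radii[1]) ** 2
            + ((z - c[2]) / radii[2]) ** 2
        )
        vent = (e <= 1.0) & (labels == Label.WM)
        labels[vent] = Label.VENTRICLE

    atlas = _build_atlas(config, labels, x, y, z, centers)

    zero = np.ones(config.grid_shape, dtype=np.float32)
    truth = GroundTruth(
        labels=labels,
        atlas=atlas,
        spacing=config.spacing_mm,
        config=config,
        contrast_t1=zero,
        contrast_t2=zero.copy(),
        true_lesion_volumes=_empty_lesion_table(),
        true_enlargement_ml={"left": 0.0, "right": 0.0},
        true_thickness_mm={rid: t for rid in atlas.ids_of_class(RegionClass.CORTICAL)},
        radial_mm=radial,
        pial_offset_mm=pial_offset,
        ventricle_centers_mm=centers,
    )
    return truth


def _empty_lesion_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["region_id", "lesion_class", "volume_mL"]).astype(
        {"region_id": int, "lesion_class": str, "volume_mL": float}
    )


def _build_atlas(config, labels, x, y, z, centers) -> RegionAtlas:
    """Angular-sector parcellation: 8 cortical, 4 WM, 8 deep-GM, 2 ventricle."""
    atlas = np.zeros(config.grid_shape, dtype=np.int16)
    rows = []

    sector = _cortical_sector(x, y, z)
    gm = labels == Label.GM
    for s in range(8):
        rid = 101 + s
        atlas[gm & (sector == s)] = rid
        rows.append((rid, f"cortical_sector_{s}", RegionClass.CORTICAL))

    # deep grey matter: periventricular ring sectors, 4 anatomies per side
    wm = labels == Label.WM
    ring_mm = 4.0
    deep = np.zeros_like(wm)
    for k, side in enumerate(("left", "right")):
        c = centers[side]
        vent_side = (labels == Label.VENTRICLE) & ((x < 0) if side == "left" else (x >= 0))
        dist = ndimage.distance_transform_edt(~vent_side, sampling=config.spacing_mm)
        ring = wm & (dist <= ring_mm) & ~deep
        phi = np.arctan2(z - c[2], y - c[1])
        quad = np.clip(((phi + np.pi) / (np.pi / 2)).astype(int), 0, 3)
        for q in range(4):
            rid = 301 + 4 * k + q
            atlas[ring & (quad == q)] = rid
            rows.append((rid, f"{side}_{DEEP_GM_NAMES[q]}", RegionClass.DEEP_GREY))
        deep |= ring

    # remaining WM by azimuth quadrant
    theta = np.arctan2(y, x)
    itheta = np.clip(((theta + np.pi) / (np.pi / 2)).astype(int), 0, 3)
    wm_rest = wm & ~deep
    for q in range(4):
        rid = 201 + q
        atlas[wm_rest & (itheta == q)] = rid
        rows.append((rid, f"wm_sector_{q}", RegionClass.WHITE_MATTER))

    for k, side in enumerate(("left", "right")):
        rid = 401 + k
        vent_side = (labels == Label.VENTRICLE) & ((x < 0) if side == "left" else (x >= 0))
        atlas[vent_side] = rid
        rows.append((rid, f"{side}_lateral_ventricle", RegionClass.VENTRICLE))

    table = pd.DataFrame(rows, columns=["region_id", "region_name", "region_class"])
    return RegionAtlas(labels=atlas, table=table, spacing=config.spacing_mm)


# ---------------------------------------------------------------------------
# injury injection
# ---------------------------------------------------------------------------


def inject_injuries(truth: GroundTruth, spec: InjurySpec, snap_mm: float = 0.0) -> GroundTruth:
    """Return a new ground truth with the requested injuries applied.

    Lesion voxels are relabelled inside their parent tissue; ventricles are
    dilated directionally into white matter until the added volume is
    reached to within one voxel; thinned regions have the GM ribbon
    rescaled from the pial surface inward.

    ``snap_mm`` > 0 moves a lesion centre to the nearest parent-tissue
    voxel within that distance (used when centres were drawn on a template
    anatomy and applied to an individually varied one); a centre farther
    than that raises :class:`PlacementError`.
    """
    out = copy.deepcopy(truth)
    if spec.empty:
        return out

    config = out.config
    x, y, z = _coordinate_grid(config)

    # cortical thinning first: operates on the pristine ribbon geometry
    for thin in spec.cortical_thinning:
        if thin.region_id not in out.true_thickness_mm:
            raise PlacementError(f"region {thin.region_id} is not a cortical region")
        region = out.atlas.mask(thin.region_id)
        t = config.gm_thickness_mm
        keep_depth = thin.thickness_scale * t
        # GM deeper than the rescaled ribbon becomes WM
        strip = (
            region
            & (out.labels == Label.GM)
            & (out.radial_mm < out.pial_offset_mm - keep_depth)
        )
        out.labels[strip] = Label.WM
        out.true_thickness_mm[thin.region_id] = keep_depth

    for lesion in spec.lesions:
        _apply_lesion(out, lesion, x, y, z, snap_mm)

    for enl in spec.ventricle_enlargement:
        _apply_enlargement(out, enl, x, y, z)

    out.true_lesion_volumes = _lesion_volume_table(out)
    return out


def _apply_lesion(truth: GroundTruth, lesion: LesionSpec, x, y, z, snap_mm: float = 0.0) -> None:
    parent = Label.WM if lesion.tissue == "WM" else Label.GM
    new_label = Label.WM_LESION if lesion.tissue == "WM" else Label.GM_LESION
    cx, cy, cz = lesion.center_mm
    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    centre_idx = np.unravel_index(np.argmin(d2), d2.shape)
    # a centre inside an earlier lesion of the same class simply merges
    if truth.labels[centre_idx] not in (parent, new_label):
        snapped = False
        if snap_mm > 0:
            parent_mask = truth.labels == parent
            dist, nearest = ndimage.distance_transform_edt(
                ~parent_mask, sampling=truth.spacing, return_indices=True
            )
            if dist[centre_idx] <= snap_mm:
                ci = tuple(int(nearest[a][centre_idx]) for a in range(3))
                cx, cy, cz = x[ci], y[ci], z[ci]
                d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
                snapped = True
        if not snapped:
            raise PlacementError(
                f"lesion centre {lesion.center_mm} lies in "
                f"{Label(truth.labels[centre_idx]).name}, not {lesion.tissue}"
            )
    sphere = (d2 <= lesion.radius_mm**2) & (truth.labels == parent)
    truth.labels[sphere] = new_label
    truth.contrast_t1[sphere] = lesion.contrast[0]
    truth.contrast_t2[sphere] = lesion.contrast[1]


def _apply_enlargement(truth: GroundTruth, enl: EnlargementSpec, x, y, z) -> None:
    if enl.added_volume_ml == 0:
        return
    target_voxels = int(round(enl.added_volume_ml * 1000.0 / truth.voxel_volume_mm3))
    side_sign = -1 if enl.side == "left" else 1
    centre = truth.ventricle_centers_mm[enl.side]
    vent = (truth.labels == Label.VENTRICLE) & (side_sign * x >= 0)
    direction = None
    if enl.direction is not None:
        d = np.asarray(enl.direction, dtype=float)
        n = np.linalg.norm(d)
        direction = d / n if n > 0 else None

    struct = ndimage.generate_binary_structure(3, 1)
    cone_cos = enl.cone_cos  # growth restricted to a directional cone when possible
    grown = vent.copy()
    added = 0
    while added < target_voxels:
        layer = ndimage.binary_dilation(grown, structure=struct) & (truth.labels == Label.WM)
        if not layer.any():
            break
        idx = np.argwhere(layer)
        pts = np.stack(
            [x[tuple(idx.T)] - centre[0], y[tuple(idx.T)] - centre[1], z[tuple(idx.T)] - centre[2]],
            axis=1,
        )
        norms = np.linalg.norm(pts, axis=1)
        if direction is not None:
            cosang = pts @ direction / np.maximum(norms, 1e-9)
            sel = cosang >= cone_cos
            if not sel.any():
                sel = np.ones(len(idx), dtype=bool)  # relax when the lobe is blocked
            idx, cosang, norms = idx[sel], cosang[sel], norms[sel]
            # closest-first within the cone keeps the lobe compact
            order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -cosang, np.round(norms, 3)))
        else:
            order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], np.round(norms, 3)))
        take = min(target_voxels - added, len(order))
        chosen = idx[order[:take]]
        grown[tuple(chosen.T)] = True
        truth.labels[tuple(chosen.T)] = Label.VENTRICLE
        if truth.enlargement_mask is None:
            truth.enlargement_mask = np.zeros(truth.labels.shape, dtype=bool)
        truth.enlargement_mask[tuple(chosen.T)] = True
        added += take
    truth.true_enlargement_ml[enl.side] = (
        truth.true_enlargement_ml.get(enl.side, 0.0)
        + added * truth.voxel_volume_mm3 / 1000.0
    )


def _lesion_volume_table(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    vox_ml = truth.voxel_volume_mm3 / 1000.0
    for label, cls_name in ((Label.WM_LESION, "WM-lesion"), (Label.GM_LESION, "GM-lesion")):
        mask = truth.labels == label
        if not mask.any():
            continue
        ids, counts = np.unique(truth.atlas.labels[mask], return_counts=True)
        for rid, n in zip(ids, counts):
            rows.append((int(rid), cls_name, float(n) * vox_ml))
    if not rows:
        return _empty_lesion_table()
    return pd.DataFrame(rows, columns=["region_id", "lesion_class", "volume_mL"])


# ---------------------------------------------------------------------------
# MR simulation
# ---------------------------------------------------------------------------


def _bias_field(shape, order: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    axes = [np.linspace(-1, 1, n) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    p = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue
                p += rng.normal() * (xx**i) * (yy**j) * (zz**k)
    p -= p.mean()
    peak = np.abs(p).max()
    if peak > 0:
        p /= peak
    return (1.0 + amplitude * p).astype(np.float32)


def simulate_mri(truth: GroundTruth, acq: AcquisitionSpec) -> tuple[ImageVolume, ImageVolume]:
    """Simulate co-registered T1- and T2-like volumes from the ground truth."""
    present = np.unique(truth.labels)
    for means in (acq.tissue_means_t1, acq.tissue_means_t2):
        missing = [int(l) for l in present if int(l) not in means]
        if missing:
            raise KeyError(f"missing tissue intensity for labels {missing}")

    rng = np.random.default_rng(acq.seed)
    volumes = []
    for modality, means, contrast, sigma in (
        ("T1", acq.tissue_means_t1, truth.contrast_t1, acq.noise_sigma[0]),
        ("T2", acq.tissue_means_t2, truth.contrast_t2, acq.noise_sigma[1]),
    ):
        lut = np.zeros(int(present.max()) + 1, dtype=np.float64)
        for lab, mean in means.items():
            if lab <= present.max():
                lut[lab] = mean
        img = lut[truth.labels] * contrast
        if acq.tissue_sds:
            sd_lut = np.zeros_like(lut)
            for lab, sd in acq.tissue_sds.items():
                if lab <= present.max():
                    sd_lut[lab] = sd
            sd_map = sd_lut[truth.labels]
            if sd_map.any():
                img = img + rng.normal(size=img.shape) * sd_map
        img = img * _bias_field(img.shape, acq.bias_order, acq.bias_amplitude, rng)
        if sigma > 0:
            n1 = rng.normal(scale=sigma, size=img.shape)
            n2 = rng.normal(scale=sigma, size=img.shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)
        volumes.append(ImageVolume(img.astype(np.float32), truth.spacing, modality))
    return volumes[0], volumes[1]


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class Subject:
    subject_id: str
    group: str  # "control" or "patient"
    age: float
    sex: int  # 0/1
    sequence: str  # scanner sequence, "A" or "B"
    injury: InjurySpec
    acq_seed: int
    config: PhantomConfig | None = None  # per-subject anatomy (jittered)


@dataclass
class AnatomyJitter:
    """Inter-subject anatomical variability (relative sds / ranges).

    Every subject's phantom is a jittered copy of the base configuration:
    brain and ventricle semi-axes, cortical thickness and sulcal pattern
    vary across individuals, so normative statistics and the ventricle
    shape model see realistic healthy variability rather than a single
    frozen anatomy.
    """

    brain_radii_rel_sd: float = 0.02
    gm_thickness_rel_sd: float = 0.04
    ventricle_radii_rel_sd: float = 0.08
    sulci_amplitude_rel_sd: float = 0.15
    random_phase: bool = True

    def sample(self, rng: np.random.Generator, base: PhantomConfig) -> PhantomConfig:
        cfg = copy.deepcopy(base)
        cfg.brain_radii_mm = tuple(
            float(r * (1 + rng.normal(scale=self.brain_radii_rel_sd)))
            for r in base.brain_radii_mm
        )
        cfg.gm_thickness_mm = float(
            base.gm_thickness_mm * (1 + rng.normal(scale=self.gm_thickness_rel_sd))
        )
        cfg.ventricle_radii_mm = tuple(
            tuple(float(r * (1 + rng.normal(scale=self.ventricle_radii_rel_sd))) for r in side)
            for side in base.ventricle_radii_mm
        )
        if cfg.sulci is not None and cfg.sulci.amplitude_mm > 0:
            cfg.sulci = copy.deepcopy(cfg.sulci)
            cfg.sulci.amplitude_mm = float(
                max(0.2, cfg.sulci.amplitude_mm * (1 + rng.normal(scale=self.sulci_amplitude_rel_sd)))
            )
            if self.random_phase:
                cfg.sulci.phase = float(rng.uniform(0, 2 * np.pi))
        return cfg


@dataclass
class InjurySampler:
    """Distribution of injuries among patients.

    The three injury types are drawn independently at the cohort rates
    observed clinically (enlargement most common, then lesions, then
    cortical malformations); independence makes enlargement accompany
    lesions at the enlargement base rate.
    """

    p_enlargement: float = 0.68
    p_lesion: float = 0.55
    p_cortical: float = 0.30
    lesion_radius_mm: tuple[float, float] = (3.0, 7.0)
    max_lesions: int = 2
    p_gm_lesion: float = 0.3
    enlargement_ml: tuple[float, float] = (0.5, 2.5)
    thinning_scale: tuple[float, float] = (0.45, 0.8)
    thinned_regions: tuple[int, int] = (2, 3)  # regions per affected patient

    def sample(self, rng: np.random.Generator, base: GroundTruth) -> InjurySpec:
        spec = InjurySpec(seed=int(rng.integers(2**31 - 1)))
        config = base.config
        if rng.random() < self.p_lesion:
            n_lesions = 1 + int(rng.integers(self.max_lesions))
            for _ in range(n_lesions):
                tissue = "GM" if rng.random() < self.p_gm_lesion else "WM"
                radius = rng.uniform(*self.lesion_radius_mm)
                center = _sample_lesion_center(rng, base, tissue, radius)
                if center is None:
                    continue
                if tissue == "WM":
                    contrast = (rng.uniform(0.6, 0.8), rng.uniform(1.5, 1.9))
                else:
                    contrast = (rng.uniform(0.7, 0.85), rng.uniform(1.3, 1.6))
                spec.lesions.append(
                    LesionSpec(center_mm=center, radius_mm=radius, tissue=tissue, contrast=contrast)
                )
        if rng.random() < self.p_enlargement:
            sides = ["left", "right"] if rng.random() < 0.3 else [
                "left" if rng.random() < 0.5 else "right"
            ]
            for side in sides:
                d = rng.normal(size=3)
                d[1] = abs(d[1]) + 1.0  # bias toward the posterior direction
                spec.ventricle_enlargement.append(
                    EnlargementSpec(
                        side=side,
                        added_volume_ml=float(rng.uniform(*self.enlargement_ml)),
                        direction=tuple(d / np.linalg.norm(d)),
                    )
                )
        if rng.random() < self.p_cortical:
            cort = base.atlas.ids_of_class(RegionClass.CORTICAL)
            lo, hi = self.thinned_regions
            n_regions = int(rng.integers(lo, hi + 1))
            for rid in rng.choice(cort, size=min(n_regions, len(cort)), replace=False):
                spec.cortical_thinning.append(
                    ThinningSpec(region_id=int(rid), thickness_scale=float(rng.uniform(*self.thinning_scale)))
                )
        return spec


def _sample_lesion_center(rng, base: GroundTruth, tissue: str, radius: float):
    """Rejection-sample a lesion centre whose sphere fits inside the tissue."""
    target = Label.WM if tissue == "WM" else Label.GM
    mask = base.labels == target
    # keep the sphere inside the tissue where possible
    interior = ndimage.distance_transform_edt(mask, sampling=base.spacing) >= min(
        radius, 3.0 if tissue == "WM" else 1.0
    )
    pool = np.argwhere(interior if interior.any() else mask)
    if len(pool) == 0:
        return None
    idx = pool[int(rng.integers(len(pool)))]
    centre_mm = (idx - (np.array(base.labels.shape) - 1) / 2.0) * np.array(base.spacing)
    return tuple(float(v) for v in centre_mm)


def simulate_cohort(
    n_controls: int,
    n_patients: int,
    base: PhantomConfig,
    injury_sampler: InjurySampler | None = None,
    seed: int = 0,
    jitter: AnatomyJitter | None = None,
) -> list[Subject]:
    """Draw a cohort manifest: per-subject covariates, anatomy, injuries, seeds.

    Volumes are not rendered here; use :func:`realize_subject` per subject
    so cohorts of any size stream through the pipeline.  Controls carry an
    empty injury spec; every subject gets an anatomically jittered copy of
    the base configuration; ages are Uniform(5, 17) years, sex
    Bernoulli(0.5), scanner sequence A/B at equal rates.
    """
    if n_controls < 0 or n_patients < 0:
        raise ValueError("cohort counts must be >= 0")
    sampler = injury_sampler or InjurySampler()
    jit = AnatomyJitter() if jitter is None else jitter
    rng = np.random.default_rng(seed)
    base_truth = build_anatomy(base) if n_patients else None
    subjects: list[Subject] = []
    for i in range(n_controls + n_patients):
        is_control = i < n_controls
        group = "control" if is_control else "patient"
        injury = InjurySpec() if is_control else sampler.sample(rng, base_truth)
        subjects.append(
            Subject(
                subject_id=f"sub-{i:03d}",
                group=group,
                age=float(rng.uniform(5, 17)),
                sex=int(rng.integers(2)),
                sequence="A" if rng.random() < 0.5 else "B",
                injury=injury,
                acq_seed=int(rng.integers(2**31 - 1)),
                config=jit.sample(rng, base),
            )
        )
    return subjects


def cohort_manifest(subjects: list[Subject]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "sequence": s.sequence,
            "n_lesions": len(s.injury.lesions),
            "n_enlargements": len(s.injury.ventricle_enlargement),
            "n_thinned_regions": len(s.injury.cortical_thinning),
            "acq_seed": s.acq_seed,
        }
        for s in subjects
    ]
    return pd.DataFrame(rows)


def realize_subject(
    subject: Subject,
    base: PhantomConfig,
    acq: AcquisitionSpec,
    base_truth: GroundTruth | None = None,
) -> tuple[GroundTruth, ImageVolume, ImageVolume]:
    """Render one subject's ground truth and MR volumes.

    ``base_truth`` may carry a precomputed control anatomy so repeated
    calls on the same anatomy skip the rebuild; it is ignored when the
    subject carries its own (jittered) configuration.
    """
    if subject.config is not None:
        anatomy = build_anatomy(subject.config)
    elif base_truth is not None:
        anatomy = base_truth
    else:
        anatomy = build_anatomy(base)
    truth = inject_injuries(anatomy, subject.injury, snap_mm=3.0)
    acq_i = copy.deepcopy(acq)
    acq_i.seed = subject.acq_seed
    t1, t2 = simulate_mri(truth, acq_i)
    return truth, t1, t2


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------


@dataclass
class ScoreGeneratorSpec:
    """Sparse non-positive linear model generating one clinical score."""

    weights: dict[str, float]
    intercept: float = 0.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    sequence_effect: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.weights.items() if v > 0}
        if bad:
            raise ValueError(f"biomarker weights must be <= 0, got {bad}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_clinical_scores(
    table: pd.DataFrame, generators: dict[str, ScoreGeneratorSpec]
) -> pd.DataFrame:
    """Generate clinical scores from a biomarker table.

    ``table`` must contain every feature named in the generator weights
    plus the covariates ``age``, ``sex`` and ``sequence``.  Returns a frame
    indexed like ``table`` with one column per score.
    """
    out = pd.DataFrame(index=table.index)
    seq_numeric = (table["sequence"] == "B").astype(float) if "sequence" in table else 0.0
    for name, gen in generators.items():
        unknown = [f for f in gen.weights if f not in table.columns]
        if unknown:
            raise KeyError(f"score {name}: unknown biomarker features {unknown}")
        rng = np.random.default_rng(gen.seed)
        score = np.full(len(table), gen.intercept, dtype=float)
        for feat, w in gen.weights.items():
            score += w * table[feat].to_numpy(dtype=float)
        if "age" in table:
            score += gen.age_effect * table["age"].to_numpy(dtype=float)
        if "sex" in table:
            score += gen.sex_effect * table["sex"].to_numpy(dtype=float)
        score += gen.sequence_effect * np.asarray(seq_numeric, dtype=float)
        if gen.noise_sd > 0:
            score += rng.normal(scale=gen.noise_sd, size=len(table))
        out[name] = score
    return out


def default_score_generators(
    table: pd.DataFrame,
    target_r2: float = 0.7,
    n_features: int = 3,
    seed: int = 0,
    min_affected_frac: float = 0.06,
) -> dict[str, ScoreGeneratorSpec]:
    """Build six score generators with clinically scaled negative weights.

    For each score a few injury features are selected among those with
    genuine cohort variability (nonzero in at least ``min_affected_frac``
    of subjects); lesion/enlargement (mL) features get weights of order
    0.1-1 per mL and shape (|z|) features of order 1-15 per z unit,
    rescaled so each selected feature contributes comparable variance.
    Covariate effects are scaled to a modest fraction of the biomarker
    signal, and the noise sd is calibrated on the full predictable
    variance (biomarkers + covariates) so the generated score has the
    requested coefficient of determination against its linear predictor.
    """
    rng = np.random.default_rng(seed)
    covars = {"age", "sex", "sequence", "subject_id", "group"}
    feature_cols = [c for c in table.columns if c not in covars]
    sds = table[feature_cols].std()
    nonzero_frac = (table[feature_cols].abs() > 1e-9).mean()
    usable = [
        c for c in feature_cols
        if sds[c] > 1e-3 and nonzero_frac[c] >= min_affected_frac
    ]
    if not usable:
        usable = [c for c in feature_cols if sds[c] > 1e-9] or feature_cols
    generators: dict[str, ScoreGeneratorSpec] = {}
    for name in SCORE_NAMES:
        feats = list(rng.choice(usable, size=min(n_features, len(usable)), replace=False))
        weights = {}
        for f in feats:
            if "lesion" in f or "enlargement" in f:
                w = -rng.uniform(0.1, 1.0)
            else:
                w = -rng.uniform(1.0, 15.0)
            # rescale so each feature contributes comparable score variance
            contrib = abs(w) * sds[f]
            target_contrib = 5.0
            w *= target_contrib / max(contrib, 1e-9)
            weights[f] = float(w)
        signal = np.zeros(len(table))
        for f, w in weights.items():
            signal += w * table[f].to_numpy(dtype=float)
        signal_sd = max(signal.std(), 1e-9)
        # covariates explain a modest share of outcome variance
        age_sd = table["age"].std() if "age" in table else 3.5
        age_effect = float(rng.uniform(0.05, 0.15)) * signal_sd / max(age_sd, 1e-9)
        sex_effect = float(rng.uniform(-0.3, 0.3)) * signal_sd
        seq_effect = float(rng.uniform(-0.3, 0.3)) * signal_sd
        predictable_var = (
            signal_sd**2
            + (age_effect * age_sd) ** 2
            + (sex_effect * 0.5) ** 2
            + (seq_effect * 0.5) ** 2
        )
        noise_sd = np.sqrt(predictable_var * (1 - target_r2) / target_r2)
        generators[name] = ScoreGeneratorSpec(
            weights=weights,
            intercept=100.0,
            age_effect=age_effect,
            sex_effect=sex_effect,
            sequence_effect=seq_effect,
            noise_sd=float(noise_sd),
            seed=int(rng.integers(2**31 - 1)),
        )
    return generators
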