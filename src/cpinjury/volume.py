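"""Core spatial containers: scalar volumes and region atlases.

Volumes are stored as plain numpy arrays with an explicit voxel spacing in
millimetres and a modality tag.  World coordinates are voxel index times
spacing (RAS-oriented affine on disk); all volume arithmetic in the package
is done in this canonical frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "ImageVolume",
    "RegionAtlas",
    "RegionClass",
    "read_volume",
    "write_volume",
    "FormatError",
]


class FormatError(ValueError):
    """Raised for malformed or unusable image files."""


class Label(IntEnum):
    """Tissue labels of the phantom ground truth."""

    BACKGROUND = 0
    SKULL = 1
    CSF = 2
    GM = 3
    WM = 4
    VENTRICLE = 5
    WM_LESION = 6
    GM_LESION = 7


#: atlas region classes
class RegionClass:
    CORTICAL = "cortical"
    DEEP_GREY = "deep-grey"
    WHITE_MATTER = "white-matter"
    VENTRICLE = "ventricle"
    OTHER = "other"


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing (mm) and a modality tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same grid and modality, new array."""
        return replace(self, data=np.asarray(data))

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class RegionAtlas:
    """Integer label grid plus a label table.

    The table has columns ``region_id``, ``region_name`` and
    ``region_class`` (one of cortical / deep-grey / white-matter /
    ventricle / other) and provides the spatial frame for every regional
    biomarker.
    """

    labels: np.ndarray
    table: pd.DataFrame
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        required = {"region_id", "region_name", "region_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        self.spacing = tuple(float(s) for s in self.spacing)

    def ids_of_class(self, region_class: str) -> list[int]:
        sel = self.table.loc[self.table["region_class"] == region_class, "region_id"]
        return [int(i) for i in sel]

    def name_of(self, region_id: int) -> str:
        row = self.table.loc[self.table["region_id"] == region_id, "region_name"]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row.iloc[0])

    def mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1 with an RAS diagonal affine."""
    img = nib.Nifti1Image(np.asarray(vol.data), _affine_from_spacing(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path, modality: str = "unknown") -> ImageVolume:
    """Read a NIfTI-1 volume, normalising orientation to the closest RAS frame.

    Spacing is extracted from the affine; a non-invertible affine is a
    format error.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path}: {exc}") from exc
    affine = img.affine
    if affine is None or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise FormatError(f"{path}: non-invertible affine")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(data=data, spacing=tuple(float(z) for z in zooms), modality=modality)
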