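"""Per-subject biomarker vectors, binary injury rules and cohort prevalence.

The biomarker vector concatenates the three injury families —

* ``shape__<region>__<metric>``: absolute regional z-scores of cortical
  thickness / curvature / sulcal depth,
* ``lesion__<region>__<class>``: lesion volume (mL) per atlas region,
* ``enlargement__<anatomy>``: localized ventricular enlargement (mL)
  attributed to each deep grey matter anatomy,

plus the covariates age, sex and scanner sequence.  Binary injury presence
follows fixed rules (any lesion or enlargement volume above a one-voxel
floor; any shape |z| above 2.5), and cohort prevalence is an eight-cell
Venn decomposition over the three injury classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .volume import RegionAtlas, RegionClass

__all__ = [
    "InjuryProfile",
    "PrevalenceSummary",
    "feature_names_for_atlas",
    "assemble_table",
    "classify_injury",
    "cohort_prevalence",
    "SHAPE_PREFIX",
    "LESION_PREFIX",
    "ENLARGEMENT_PREFIX",
    "Z_THRESHOLD",
]

SHAPE_PREFIX = "shape__"
LESION_PREFIX = "lesion__"
ENLARGEMENT_PREFIX = "enlargement__"
COVARIATES = ("age", "sex", "sequence")

#: |z| above which a regional cortical shape counts as a malformation
Z_THRESHOLD = 2.5


@dataclass(frozen=True)
class InjuryProfile:
    has_cortical_malformation: bool
    has_lesion: bool
    has_ventricular_enlargement: bool

    @property
    def any_injury(self) -> bool:
        return self.has_cortical_malformation or self.has_lesion or self.has_ventricular_enlargement

    @property
    def key(self) -> tuple[bool, bool, bool]:
        return (
            self.has_cortical_malformation,
            self.has_lesion,
            self.has_ventricular_enlargement,
        )


@dataclass
class PrevalenceSummary:
    """Eight-cell Venn decomposition of injury prevalence."""

    cells: dict[tuple[bool, bool, bool], int]
    n: int

    @property
    def totals(self) -> dict[str, int]:
        return {
            "cortical": sum(c for k, c in self.cells.items() if k[0]),
            "lesion": sum(c for k, c in self.cells.items() if k[1]),
            "enlargement": sum(c for k, c in self.cells.items() if k[2]),
        }

    @property
    def n_injured(self) -> int:
        return self.n - self.cells.get((False, False, False), 0)

    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * v / self.n for k, v in self.totals.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cortical": k[0],
                "lesion": k[1],
                "enlargement": k[2],
                "count": c,
                "percent": 100.0 * c / self.n,
            }
            for k, c in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def feature_names_for_atlas(atlas: RegionAtlas) -> list[str]:
    """The canonical biomarker column set for an atlas (stable order)."""
    from .cortical import SHAPE_METRICS

    names: list[str] = []
    for rid in atlas.ids_of_class(RegionClass.CORTICAL):
        for metric in SHAPE_METRICS:
            names.append(f"{SHAPE_PREFIX}{atlas.name_of(rid)}__{metric}")
    for rid in atlas.ids_of_class(RegionClass.CORTICAL) + atlas.ids_of_class(RegionClass.DEEP_GREY):
        names.append(f"{LESION_PREFIX}{atlas.name_of(rid)}__GM")
    for rid in atlas.ids_of_class(RegionClass.WHITE_MATTER):
        names.append(f"{LESION_PREFIX}{atlas.name_of(rid)}__WM")
    for rid in atlas.ids_of_class(RegionClass.DEEP_GREY):
        names.append(f"{ENLARGEMENT_PREFIX}{atlas.name_of(rid)}")
    return names


def assemble_table(subject_rows: list[dict]) -> pd.DataFrame:
    """Assemble per-subject biomarker dicts into a rectangular table.

    Every row must provide the same feature set (missing regional values
    are allowed as NaN, never silently zero-filled); inconsistent feature
    sets raise a schema error.
    """
    if not subject_rows:
        raise ValueError("no subjects to assemble")
    keys = set(subject_rows[0])
    for i, row in enumerate(subject_rows[1:], start=1):
        if set(row) != keys:
            extra = set(row) ^ keys
            raise ValueError(f"subject {i} has inconsistent feature set: {sorted(extra)[:5]} ...")
    table = pd.DataFrame(subject_rows)
    if "subject_id" in table.columns:
        table = table.set_index("subject_id")
    return table


def classify_injury(
    vector: pd.Series | dict,
    voxel_volume_mm3: float = 1.0,
    z_threshold: float = Z_THRESHOLD,
) -> InjuryProfile:
    """Binary injury presence from one biomarker vector.

    A lesion or enlargement counts as present when any volume exceeds one
    voxel volume (an explicit floor keeping "greater than 0 mL" meaningful
    under discretisation); a cortical malformation when any regional shape
    |z| exceeds ``z_threshold``.  Missing families raise.
    """
    v = pd.Series(vector, dtype=object)
    floor_ml = voxel_volume_mm3 / 1000.0
    families = {
        SHAPE_PREFIX: [k for k in v.index if str(k).startswith(SHAPE_PREFIX)],
        LESION_PREFIX: [k for k in v.index if str(k).startswith(LESION_PREFIX)],
        ENLARGEMENT_PREFIX: [k for k in v.index if str(k).startswith(ENLARGEMENT_PREFIX)],
    }
    for prefix, cols in families.items():
        if not cols:
            raise ValueError(f"biomarker vector has no {prefix!r} features")
        if pd.isna(pd.to_numeric(v[cols], errors="coerce")).any():
            raise ValueError(f"missing values in {prefix!r} family")
    shape_vals = pd.to_numeric(v[families[SHAPE_PREFIX]])
    lesion_vals = pd.to_numeric(v[families[LESION_PREFIX]])
    enlarge_vals = pd.to_numeric(v[families[ENLARGEMENT_PREFIX]])
    return InjuryProfile(
        has_cortical_malformation=bool((shape_vals.abs() > z_threshold).any()),
        has_lesion=bool((lesion_vals > floor_ml).any()),
        has_ventricular_enlargement=bool((enlarge_vals > floor_ml).any()),
    )


def cohort_prevalence(profiles: list[InjuryProfile]) -> PrevalenceSummary:
    """Exact Venn-cell counts over a cohort of injury profiles."""
    if not profiles:
        raise ValueError("empty cohort")
    cells = {k: 0 for k in product((False, True), repeat=3)}
    for p in profiles:
        cells[p.key] += 1
    return PrevalenceSummary(cells=cells, n=len(profiles))
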