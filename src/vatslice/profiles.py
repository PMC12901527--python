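"""Per-slice VAT profiles and their standardization to the anatomical grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import AnatomicalGrid, DEFAULT_GRID
from .landmarks import SpineLandmarks, build_caudal_scale

DEFAULT_SPACING_MM = (1.4, 1.4, 3.0)


@dataclass
class SliceProfile:
    """Cross-sectional VAT area per axial slice, caudal -> cranial.

    Attributes
    ----------
    areas_cm2:
        VAT area of each slice in cm².
    slice_thickness_cm:
        Axial slice thickness (default 0.3 cm, i.e. 3 mm partitions).
    """

    areas_cm2: np.ndarray
    slice_thickness_cm: float = 0.3

    def __post_init__(self) -> None:
        self.areas_cm2 = np.asarray(self.areas_cm2, dtype=float)
        if self.slice_thickness_cm <= 0:
            raise ValueError("slice thickness must be positive")
        if not np.all(np.isfinite(self.areas_cm2)):
            raise ValueError("slice areas must be finite")
        if np.any(self.areas_cm2 < 0):
            raise ValueError("slice areas must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.areas_cm2.size

    @property
    def slice_centers_mm(self) -> np.ndarray:
        dz = self.slice_thickness_cm * 10.0
        return (np.arange(self.n_slices) + 0.5) * dz

    @property
    def vat_total_l(self) -> float:
        """Total VAT volume in liters (sum of area x thickness)."""
        return float(self.areas_cm2.sum() * self.slice_thickness_cm / 1000.0)

    @property
    def is_empty(self) -> bool:
        return self.areas_cm2.sum() == 0.0

    @property
    def fractions(self) -> np.ndarray:
        """Per-slice fraction of total VAT; NaN everywhere for an empty mask
        (fractions are undefined and flagged rather than raised)."""
        total = self.areas_cm2.sum()
        if total == 0.0:
            return np.full(self.n_slices, np.nan)
        return self.areas_cm2 / total


def compute_slice_areas(
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
) -> SliceProfile:
    """Per-slice VAT area from a binary mask volume.

    ``mask`` has shape (nx, ny, nz) with the axial axis last.  The area of
    slice *i* is the voxel count times the in-plane voxel area
    (dx*dy / 100 cm²); e.g. 100 voxels at 1.4 x 1.4 mm give 1.96 cm².
    """
    dx, dy, dz = (float(s) for s in spacing_mm)
    if min(dx, dy, dz) <= 0:
        raise ValueError("voxel spacing must be positive")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("VAT mask must be binary (0/1)")
    counts = (mask != 0).sum(axis=(0, 1))
    areas = counts * dx * dy / 100.0
    return SliceProfile(areas_cm2=areas, slice_thickness_cm=dz / 10.0)


def standardize_profile(
    profile: SliceProfile,
    landmarks: SpineLandmarks,
    grid: AnatomicalGrid = DEFAULT_GRID,
) -> pd.Series:
    """Standardize a slice profile to the anatomical grid.

    Returns the percentage of total VAT per slice (%) at each grid
    location.  Vertebral-body and disc locations read the axial slice
    nearest the landmark; the equidistant caudal points linearly
    interpolate the per-slice areas (pixel counts and areas differ only by
    a constant, so interpolating either gives identical percentages).

    Raises if the profile is empty or a landmark falls outside the axial
    coverage of the profile.
    """
    if profile.is_empty:
        raise ValueError("cannot standardize an empty profile "
                         "(total VAT is zero, fractions undefined)")
    centers = profile.slice_centers_mm
    dz = profile.slice_thickness_cm * 10.0
    lo, hi = centers[0] - dz / 2.0, centers[-1] + dz / 2.0

    caudal_pos = build_caudal_scale(landmarks, grid.n_caudal)
    spine_labels = grid.vertebral[1:]  # L5/4 .. Th10 (L5 is a caudal point)
    spine_pos = np.array([landmarks[lab] for lab in spine_labels])

    outside = [
        lab
        for lab, p in zip(
            list(grid.caudal) + list(spine_labels),
            np.concatenate([caudal_pos, spine_pos]),
        )
        if not (lo <= p <= hi)
    ]
    if outside:
        raise ValueError(f"landmark location(s) outside profile coverage: "
                         f"{outside}")

    total = profile.areas_cm2.sum()

    # caudal points: linear interpolation of per-slice amounts
    caudal_vals = np.interp(caudal_pos, centers, profile.areas_cm2)

    # vertebral/disc locations: nearest axial slice
    idx = np.clip(np.round(spine_pos / dz - 0.5).astype(int),
                  0, profile.n_slices - 1)
    spine_vals = profile.areas_cm2[idx]

    values = 100.0 * np.concatenate([caudal_vals, spine_vals]) / total
    return pd.Series(values, index=list(grid.labels), name="pct_of_total")


def standardize_cohort(
    profiles: dict[str, SliceProfile],
    landmarks: dict[str, SpineLandmarks],
    grid: AnatomicalGrid = DEFAULT_GRID,
) -> pd.DataFrame:
    """Standardized profile matrix: one row per participant, 40 location
    columns (percent of total VAT) plus ``vat_total_l``."""
    rows = {}
    for pid, prof in profiles.items():
        row = standardize_profile(prof, landmarks[pid], grid)
        row["vat_total_l"] = prof.vat_total_l
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df
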