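"""Spine landmarks: container, localization from label volumes, caudal scale.

Axial coordinate convention used throughout the package: position in mm
from the most caudal acquired slice, increasing caudal -> cranial; slice
indices are 0-based and slice *i* is centred at ``(i + 0.5) * dz``.
"""

from __future__ import annotations

from collections import OrderedDict
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .grid import LANDMARK_SEQUENCE

#: integer ids used in synthetic spine label volumes (0 = background)
LANDMARK_IDS: dict[int, str] = {
    i + 1: lab for i, lab in enumerate(LANDMARK_SEQUENCE)
}


class SpineLandmarks(Mapping):
    """Ordered map of landmark label -> axial position in mm.

    Positions must strictly increase in the caudal->cranial order
    FH < L5 < L5/4 < L4 < ... < Th10; violations signal a corrupted
    segmentation and are rejected.
    """

    def __init__(self, positions: Mapping[str, float]):
        missing = [lab for lab in LANDMARK_SEQUENCE if lab not in positions]
        if missing:
            raise ValueError(f"missing landmark label(s): {missing}")
        self._pos = OrderedDict(
            (lab, float(positions[lab])) for lab in LANDMARK_SEQUENCE
        )
        vals = np.array(list(self._pos.values()))
        if not np.all(np.diff(vals) > 0):
            bad = [
                LANDMARK_SEQUENCE[i + 1]
                for i in np.nonzero(np.diff(vals) <= 0)[0]
            ]
            raise ValueError(
                f"landmark ordering violated at {bad}: positions must "
                "strictly increase caudal->cranial"
            )

    def __getitem__(self, label: str) -> float:
        return self._pos[label]

    def __iter__(self):
        return iter(self._pos)

    def __len__(self) -> int:
        return len(self._pos)

    @property
    def fh_l5_distance_cm(self) -> float:
        """Distance from the femoral-head level to the center of L5, cm."""
        return (self._pos["L5"] - self._pos["FH"]) / 10.0

    def to_frame(self, participant_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"label": list(self._pos), "position_mm": list(self._pos.values())}
        )
        if participant_id is not None:
            df.insert(0, "id", participant_id)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpineLandmarks":
        return cls(dict(zip(df["label"], df["position_mm"])))

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpineLandmarks({dict(self._pos)!r})"


def locate_landmarks(
    spine_labels: np.ndarray,
    spacing_mm: tuple[float, float, float],
    label_ids: Mapping[int, str] = LANDMARK_IDS,
) -> SpineLandmarks:
    """Locate landmark positions as the axial centroid of each label.

    Parameters
    ----------
    spine_labels:
        Integer volume of shape (nx, ny, nz) with the axial (craniocaudal)
        axis last; 0 is background.
    spacing_mm:
        Voxel spacing (dx, dy, dz) in mm.

    Returns the positions of all 16 landmarks (mm from the most caudal
    slice).  A missing label raises an error naming the label.
    """
    dz = float(spacing_mm[2])
    positions: dict[str, float] = {}
    for lid, lab in label_ids.items():
        zidx = np.nonzero(spine_labels == lid)[2]
        if zidx.size == 0:
            raise ValueError(f"spine label volume misses landmark {lab!r} "
                             f"(id {lid})")
        positions[lab] = (float(zidx.mean()) + 0.5) * dz
    return SpineLandmarks(positions)


def build_caudal_scale(landmarks: SpineLandmarks, n_points: int = 26) -> np.ndarray:
    """Equidistant axial positions (mm) from the femoral heads to L5.

    With the cohort-mean femoral-head distance of 12.9 cm and 26 points the
    step is 12.9/25 = 0.516 cm, i.e. 0.5 cm at one-decimal rounding.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    fh, l5 = landmarks["FH"], landmarks["L5"]
    if fh >= l5:
        raise ValueError("femoral-head level must lie caudal of L5")
    return np.linspace(fh, l5, n_points)
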