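"""Standardized anatomical grid for craniocaudal VAT profiles.

Profiles are matched to 40 ordered locations along the craniocaudal axis
(caudal to cranial): 26 equidistant points spanning the femoral-head level
up to the center of L5, followed by the centers of the vertebral bodies
L5..Th10 (L5 itself being the last caudal point) interleaved with the seven
intervertebral disc centers.  Indexing profiles by anatomical label rather
than absolute position removes the direct influence of body height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: vertebral-body and disc-center labels, ordered caudal -> cranial
SPINE_SEQUENCE: tuple[str, ...] = (
    "L5", "L5/4", "L4", "L4/3", "L3", "L3/2", "L2", "L2/1", "L1",
    "L1/Th12", "Th12", "Th12/11", "Th11", "Th11/10", "Th10",
)

#: all landmark labels required from a spine segmentation (adds the
#: femoral-head level as the caudal anchor)
LANDMARK_SEQUENCE: tuple[str, ...] = ("FH",) + SPINE_SEQUENCE

DEFAULT_N_CAUDAL = 26
DEFAULT_STEP_CM = 0.5  # cohort-level label step below L5


def caudal_labels(n_points: int = DEFAULT_N_CAUDAL,
                  step_cm: float = DEFAULT_STEP_CM) -> list[str]:
    """Labels for the equidistant caudal points, most caudal first.

    The k-th point below L5 is labelled ``"L5-{k*step} cm"``; the point at
    L5 itself is labelled ``"L5"``.  Labels are cohort-level: the physical
    step varies per individual with the femoral-head distance.
    """
    if n_points < 2:
        raise ValueError("caudal scale needs at least 2 points")
    out = []
    for k in range(n_points - 1, 0, -1):
        out.append(f"L5-{k * step_cm:g} cm")
    out.append("L5")
    return out


@dataclass(frozen=True)
class AnatomicalGrid:
    """The ordered set of standardized profile locations.

    Parameters
    ----------
    n_caudal:
        Number of equidistant points from the femoral heads to L5
        (inclusive of both ends).
    label_step_cm:
        Cohort-level step used only for labelling the caudal points.
    """

    n_caudal: int = DEFAULT_N_CAUDAL
    label_step_cm: float = DEFAULT_STEP_CM
    labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        labs = caudal_labels(self.n_caudal, self.label_step_cm)
        labs.extend(SPINE_SEQUENCE[1:])
        object.__setattr__(self, "labels", tuple(labs))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def caudal(self) -> tuple[str, ...]:
        return self.labels[: self.n_caudal]

    @property
    def vertebral(self) -> tuple[str, ...]:
        """The 15 vertebral-body / disc locations from L5 to Th10."""
        return self.labels[self.n_caudal - 1:]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def positions_mm(self, landmarks) -> np.ndarray:
        """Physical axial position (mm) of every grid location for one
        individual's spine geometry."""
        from .landmarks import build_caudal_scale

        caudal = build_caudal_scale(landmarks, self.n_caudal)
        spine = np.array([landmarks[lab] for lab in SPINE_SEQUENCE[1:]])
        return np.concatenate([caudal, spine])


DEFAULT_GRID = AnatomicalGrid()
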