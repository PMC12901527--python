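"""Synthetic cohort generator.

Emulates the inputs of a population-scale Dixon-MRI body-composition study:
participant covariates calibrated to published per-stratum summary
statistics, spine geometries, craniocaudal VAT density profiles with a
plantable age-independent crossing, and voxelized VAT / spine-label volumes
(axial 3 mm partitions, 1.4 x 1.4 mm in-plane).

The continuous VAT density along the craniocaudal axis is a two-component
mixture: a pelvic dome (Gaussian centred midway between the femoral heads
and the pelvic/abdominal boundary ~3 cm below L5) plus an abdominal
component (Gaussian centred at a vertebral landmark, L3 in men).  Age
modifies the profile through a multiplicative hinge gradient,
``f_age = f0 * (1 + delta * r(z))`` with ``delta`` the age in decades
relative to the model reference and ``r`` zero on one side of a pivot and
linear on the other: younger individuals carry relatively more pelvic VAT
and the balance shifts progressively toward the abdomen with age.  Because
standardized profiles are normalized per individual, age curves cross
wherever the local relative tilt equals its profile-wide mean; the hinge
crosses that level exactly once, and its pivot is solved per individual so
the crossing falls exactly on the planted grid location.  (A tilt that only
rescales the two component amplitudes cannot plant a crossing: its
normalized curves can only cross where the local component mix equals the
global mix, a location fixed by the component shapes alone.)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import AnatomicalGrid, DEFAULT_GRID
from .landmarks import LANDMARK_IDS, SpineLandmarks
from .profiles import DEFAULT_SPACING_MM, SliceProfile

SEXES = ("M", "F")
BMI_GROUPS = ("I", "II", "III", "IV", "V")
AGE_GROUPS = ("i", "ii", "iii", "iv", "v")

#: half-open BMI intervals per group; the last group is open-ended for
#: assignment but capped for sampling (observed maxima are ~54 kg/m²)
BMI_GROUP_BOUNDS = {
    "I": (18.5, 25.0),
    "II": (25.0, 30.0),
    "III": (30.0, 35.0),
    "IV": (35.0, 40.0),
    "V": (40.0, 54.0),
}

#: half-open age intervals per group (years); >=60 all map to group v and
#: the generator caps ages at 72, the oldest observed age
AGE_GROUP_BOUNDS = {
    "i": (20, 30),
    "ii": (30, 40),
    "iii": (40, 50),
    "iv": (50, 60),
    "v": (60, 73),
}

EXCLUSION_FLAGS = ("fat_water_swap", "corrupted", "missing_anthropometry")

# nominal center-to-center spacings (cm) between consecutive vertebral
# bodies L5->L4 ... Th11->Th10 at a reference height of 171.7 cm
_VERTEBRAL_GAPS_CM = np.array([3.9, 3.8, 3.7, 3.6, 3.4, 3.2, 3.0])
_REFERENCE_HEIGHT_CM = 171.7
_FH_BASE_OFFSET_MM = 15.0  # most caudal slice sits just below the femoral heads
_TRUNK_MARGIN_MM = 40.0    # coverage above Th10 up to the cardiac apex


@dataclass(frozen=True)
class CalibrationTable:
    """Per sex x BMI group moments used to draw participant covariates.

    ``table`` columns: sex, bmi_group, n, age_mean, age_sd, height_mean,
    height_sd, bmi_mean, bmi_sd, vat_mean, vat_sd (heights cm, VAT liters).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "sex", "bmi_group", "n", "age_mean", "age_sd", "height_mean",
            "height_sd", "bmi_mean", "bmi_sd", "vat_mean", "vat_sd",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"calibration table misses columns {missing}")
        for sex in SEXES:
            sub = self.table[self.table["sex"] == sex]
            if set(sub["bmi_group"]) != set(BMI_GROUPS):
                raise ValueError(
                    f"calibration must cover all five BMI groups for sex {sex}"
                )
        if (self.table["n"] <= 0).any():
            raise ValueError("calibration group sizes must be positive")
        sd_cols = [c for c in self.table.columns if c.endswith("_sd")]
        if (self.table[sd_cols] < 0).any().any():
            raise ValueError("calibration standard deviations must be >= 0")

    def row(self, sex: str, bmi_group: str) -> pd.Series:
        t = self.table
        return t[(t["sex"] == sex) & (t["bmi_group"] == bmi_group)].iloc[0]

    def sex_proportions(self) -> pd.Series:
        tot = self.table.groupby("sex")["n"].sum()
        return tot / tot.sum()

    def group_proportions(self, sex: str) -> pd.Series:
        sub = self.table[self.table["sex"] == sex].set_index("bmi_group")["n"]
        return sub / sub.sum()


def default_calibration() -> CalibrationTable:
    """Calibration reproducing the published cohort descriptives
    (n = 11,036; 5,681 men)."""
    men = {
        "n": [1690, 2733, 979, 234, 45],
        "age_mean": [48.4, 53.3, 54.4, 55.4, 54.0],
        "age_sd": [12.3, 10.8, 10.3, 9.2, 8.2],
        "height_mean": [179.0, 178.1, 177.6, 176.9, 175.3],
        "height_sd": [6.9, 6.9, 7.0, 7.1, 8.3],
        "bmi_mean": [23.1, 27.3, 32.0, 36.9, 42.4],
        "bmi_sd": [1.4, 1.4, 1.4, 1.3, 2.3],
        "vat_mean": [2.8, 5.0, 7.0, 8.7, 9.7],
        "vat_sd": [1.3, 1.7, 1.8, 2.1, 2.2],
    }
    women = {
        "n": [2577, 1676, 743, 260, 99],
        "age_mean": [49.4, 53.5, 55.0, 56.0, 54.7],
        "age_sd": [11.7, 10.7, 10.2, 9.6, 7.3],
        "height_mean": [166.0, 164.4, 163.4, 163.1, 162.3],
        "height_sd": [6.5, 6.5, 6.3, 6.4, 6.8],
        "bmi_mean": [22.3, 27.2, 32.1, 37.0, 43.8],
        "bmi_sd": [1.6, 1.4, 1.4, 1.4, 3.2],
        "vat_mean": [1.5, 2.8, 4.1, 5.1, 5.8],
        "vat_sd": [0.8, 1.1, 1.3, 1.3, 1.4],
    }
    rows = []
    for sex, d in (("M", men), ("F", women)):
        for i, g in enumerate(BMI_GROUPS):
            rows.append({"sex": sex, "bmi_group": g,
                         **{k: v[i] for k, v in d.items()}})
    return CalibrationTable(pd.DataFrame(rows))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are several sd wide here,
    so rejection is cheap and keeps all randomness on one generator)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.normal(mean, sd, need.size)
        ok = (draw >= lo) & (draw < hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _sample_ages(rng: np.random.Generator, mean: float, sd: float,
                 size: int) -> np.ndarray:
    """Ages are drawn uniformly within 10-year age groups whose weights are
    the normal(mean, sd) probability mass on each bin; published tables give
    per-stratum means +/- sd only, so group means are matched approximately."""
    from scipy import stats

    edges = np.array([20, 30, 40, 50, 60, 73], dtype=float)
    cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
    weights = np.diff(cdf)
    weights = weights / weights.sum()
    bins = rng.choice(len(weights), size=size, p=weights)
    lo = edges[bins]
    hi = edges[bins + 1]
    return np.floor(rng.uniform(lo, hi)).astype(int)


def generate_participants(
    n: int,
    seed: int,
    calib: CalibrationTable | None = None,
) -> pd.DataFrame:
    """Draw ``n`` synthetic participants from the calibration table.

    Sex and BMI-group membership follow the calibration proportions; BMI is
    truncated-normal within the group interval; weight is derived from BMI
    and height so the BMI invariant holds exactly; total VAT is log-normal
    with group moments matched (VAT is positive and right-skewed).

    Returns a cohort DataFrame with columns id, sex, age, height_cm,
    weight_kg, bmi, flag_* (all False) and vat_total_l (ground truth).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    calib = calib or default_calibration()
    rng = np.random.default_rng(seed)

    sex_p = calib.sex_proportions()
    sexes = rng.choice(sex_p.index.to_numpy(), size=n, p=sex_p.to_numpy())

    sex = np.empty(n, dtype=object)
    group = np.empty(n, dtype=object)
    age = np.empty(n, dtype=int)
    height = np.empty(n)
    bmi = np.empty(n)
    vat = np.empty(n)

    for s in SEXES:
        sel = np.nonzero(sexes == s)[0]
        if sel.size == 0:
            continue
        gp = calib.group_proportions(s)
        groups = rng.choice(gp.index.to_numpy(), size=sel.size,
                            p=gp.to_numpy())
        for g in BMI_GROUPS:
            idx = sel[groups == g]
            if idx.size == 0:
                continue
            row = calib.row(s, g)
            lo, hi = BMI_GROUP_BOUNDS[g]
            sex[idx] = s
            group[idx] = g
            bmi[idx] = _truncated_normal(
                rng, row["bmi_mean"], row["bmi_sd"], lo, hi, idx.size)
            height[idx] = _truncated_normal(
                rng, row["height_mean"], row["height_sd"],
                row["height_mean"] - 4 * row["height_sd"] - 1e-9,
                row["height_mean"] + 4 * row["height_sd"], idx.size)
            age[idx] = _sample_ages(rng, row["age_mean"], row["age_sd"],
                                    idx.size)
            m, sd = row["vat_mean"], row["vat_sd"]
            sigma2 = np.log1p((sd / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            vat[idx] = rng.lognormal(mu, np.sqrt(sigma2), idx.size)

    height = np.round(height, 1)
    weight = np.round(bmi * (height / 100.0) ** 2, 2)
    df = pd.DataFrame({
        "id": [f"P{i:06d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "height_cm": height,
        "weight_kg": weight,
        "bmi": bmi,
        "vat_total_l": vat,
    })
    for flag in EXCLUSION_FLAGS:
        df[f"flag_{flag}"] = False
    return df


def generate_balanced_stratum(
    n_per_age_group: int,
    sex: str,
    bmi_group: str,
    seed: int,
    calib: CalibrationTable | None = None,
    age_groups: tuple[str, ...] = AGE_GROUPS,
) -> pd.DataFrame:
    """Designed-experiment cohort: one sex x BMI group with equal-sized
    age groups (ages uniform within each 10-year bin).

    Covariates are drawn from the stratum's calibration moments; used for
    parameter-recovery studies where balanced age groups are wanted.
    """
    if n_per_age_group < 1:
        raise ValueError("n_per_age_group must be >= 1")
    calib = calib or default_calibration()
    row = calib.row(sex, bmi_group)
    rng = np.random.default_rng(seed)
    n = n_per_age_group * len(age_groups)
    lo, hi = BMI_GROUP_BOUNDS[bmi_group]
    bmi = _truncated_normal(rng, row["bmi_mean"], row["bmi_sd"], lo, hi, n)
    height = np.round(_truncated_normal(
        rng, row["height_mean"], row["height_sd"],
        row["height_mean"] - 4 * row["height_sd"] - 1e-9,
        row["height_mean"] + 4 * row["height_sd"], n), 1)
    ages = np.concatenate([
        rng.integers(*AGE_GROUP_BOUNDS[a], size=n_per_age_group)
        for a in age_groups
    ])
    m, sd = row["vat_mean"], row["vat_sd"]
    sigma2 = np.log1p((sd / m) ** 2)
    vat = rng.lognormal(np.log(m) - sigma2 / 2.0, np.sqrt(sigma2), n)
    df = pd.DataFrame({
        "id": [f"{sex}{bmi_group}-{i:05d}" for i in range(n)],
        "sex": sex, "age": ages, "height_cm": height,
        "weight_kg": np.round(bmi * (height / 100.0) ** 2, 2),
        "bmi": bmi, "vat_total_l": vat,
    })
    for flag in EXCLUSION_FLAGS:
        df[f"flag_{flag}"] = False
    return df


def sample_fh_distance(rng: np.random.Generator,
                       mean_cm: float = 12.9,
                       sd_cm: float = 1.1,
                       bounds_cm: tuple[float, float] = (9.0, 17.0)) -> float:
    """One L5-to-femoral-head distance, normal truncated to physical range."""
    if sd_cm == 0:
        return mean_cm
    while True:
        d = rng.normal(mean_cm, sd_cm)
        if bounds_cm[0] <= d <= bounds_cm[1]:
            return float(d)


def generate_geometry(
    record,
    seed: int,
    distance_mean_cm: float = 12.9,
    distance_sd_cm: float = 1.1,
    distance_bounds_cm: tuple[float, float] = (9.0, 17.0),
    spacing_jitter: float = 0.03,
) -> SpineLandmarks:
    """Spine landmark positions for one participant.

    The L5-femoral-head distance is drawn Normal(12.9, 1.1) cm truncated to
    9-17 cm; vertebral spacings scale with body height and receive a small
    log-normal jitter.  Positions are mm from the most caudal slice.
    """
    height = float(record["height_cm"])
    if not np.isfinite(height) or height <= 0:
        raise ValueError("record has invalid height")
    rng = np.random.default_rng(seed)
    d_cm = sample_fh_distance(rng, distance_mean_cm, distance_sd_cm,
                              distance_bounds_cm)
    scale = height / _REFERENCE_HEIGHT_CM
    gaps = _VERTEBRAL_GAPS_CM * scale
    if spacing_jitter > 0:
        gaps = gaps * rng.lognormal(0.0, spacing_jitter, gaps.size)

    pos = {"FH": _FH_BASE_OFFSET_MM}
    pos["L5"] = pos["FH"] + d_cm * 10.0
    vertebrae = ["L5", "L4", "L3", "L2", "L1", "Th12", "Th11", "Th10"]
    for i, gap in enumerate(gaps):
        pos[vertebrae[i + 1]] = pos[vertebrae[i]] + gap * 10.0
    discs = ["L5/4", "L4/3", "L3/2", "L2/1", "L1/Th12", "Th12/11", "Th11/10"]
    for i, disc in enumerate(discs):
        pos[disc] = 0.5 * (pos[vertebrae[i]] + pos[vertebrae[i + 1]])
    return SpineLandmarks(pos)


def trunk_extent_mm(geometry: SpineLandmarks) -> float:
    """Axial extent of the covered trunk (femoral heads to cardiac apex)."""
    return geometry["Th10"] + _TRUNK_MARGIN_MM


@dataclass(frozen=True)
class ProfileModel:
    """Parameters of the craniocaudal VAT density model for one stratum.

    ``pelvic_plateau`` and ``abdominal_peak_height`` are relative component
    weights (fraction per cm before normalization); only their ratio matters
    because every profile is normalized over the covered trunk.
    ``age_slope_pelvic`` is the mean relative change of the VAT profile per
    decade of age, signed for the pelvic side (negative: younger
    individuals carry more pelvic VAT); the abdominal side changes with the
    opposite sign.  When ``planted_intersection`` is set and
    ``age_slope_abdominal`` is None, the hinge of the age gradient is
    pivoted per individual so that all age curves agree exactly at that
    grid location.  Setting
    ``age_slope_abdominal`` explicitly switches to an amplitude-only tilt
    (pelvic and abdominal components rescaled independently) whose crossing
    is emergent rather than planted.
    """

    pelvic_plateau: float
    abdominal_peak_height: float
    abdominal_peak_location: str = "L3"
    boundary_offset_cm: float = 3.0
    age_slope_pelvic: float = -0.08
    age_slope_abdominal: float | None = None
    planted_intersection: str | None = None
    noise_sd: float = 0.0
    shape_jitter: float = 0.0
    abdominal_sigma_cm: float = 4.0
    abdominal_sigma_up_cm: float = 8.0  # heavier cranial shoulder: VAT keeps
    pelvic_width_factor: float = 3.2    # a sizeable share up to Th10
    age_ref_years: float = 45.0

    def __post_init__(self) -> None:
        if self.pelvic_plateau < 0 or self.abdominal_peak_height < 0:
            raise ValueError("component heights must be >= 0")
        if self.noise_sd < 0 or self.shape_jitter < 0:
            raise ValueError("noise parameters must be >= 0")
        if (self.abdominal_sigma_cm <= 0 or self.abdominal_sigma_up_cm <= 0
                or self.boundary_offset_cm < 0):
            raise ValueError("invalid model geometry parameter")
        if abs(self.age_slope_pelvic) >= 0.15:
            raise ValueError("age_slope_pelvic too large: density would "
                             "turn negative within the 20-72 year range")

    def replace(self, **kw) -> "ProfileModel":
        return dataclasses.replace(self, **kw)


#: default per-stratum models: pelvic level decreases and the abdominal
#: peak increases with BMI; in women the peak shifts from L5/4 to L3 with
#: increasing BMI and the pelvic level is generally higher than in men.
#: Planted crossings follow the reference locations of the real cohort.
_MEN_DEFAULTS = dict(
    plateau=[0.026, 0.024, 0.022, 0.020, 0.018],
    peak=[0.036, 0.043, 0.050, 0.057, 0.064],
    peak_loc=["L3"] * 5,
    crossing=["L5/4", "L5-1 cm", "L5-2.5 cm", "L2/1", "L5-7 cm"],
)
_WOMEN_DEFAULTS = dict(
    plateau=[0.032, 0.030, 0.028, 0.026, 0.024],
    peak=[0.036, 0.042, 0.048, 0.054, 0.060],
    peak_loc=["L5/4", "L4", "L4/3", "L3", "L3"],
    crossing=["L5", "L5-2.5 cm", "L1", "L2/1", "L1"],
)
DEFAULT_NOISE_SD = 0.0025      # fraction per cm, per-slice measurement noise
DEFAULT_SHAPE_JITTER = 0.25    # inter-individual component-weight variation


def default_profile_models(
    noise_sd: float = DEFAULT_NOISE_SD,
    shape_jitter: float = DEFAULT_SHAPE_JITTER,
) -> dict[tuple[str, str], ProfileModel]:
    """Per (sex, BMI group) profile models for the default synthetic study."""
    models = {}
    for sex, d in (("M", _MEN_DEFAULTS), ("F", _WOMEN_DEFAULTS)):
        for i, g in enumerate(BMI_GROUPS):
            models[(sex, g)] = ProfileModel(
                pelvic_plateau=d["plateau"][i],
                abdominal_peak_height=d["peak"][i],
                abdominal_peak_location=d["peak_loc"][i],
                planted_intersection=d["crossing"][i],
                noise_sd=noise_sd,
                shape_jitter=shape_jitter,
            )
    return models


def _location_position_mm(label: str, geometry: SpineLandmarks,
                          grid: AnatomicalGrid) -> float:
    """Physical position of a grid label for one individual."""
    positions = grid.positions_mm(geometry)
    return float(positions[grid.index(label)])


def _readout_weights(label: str, geometry: SpineLandmarks,
                     grid: AnatomicalGrid,
                     centers_mm: np.ndarray) -> np.ndarray:
    """Linear functional (weights over slices) reproducing how the
    standardization reads a grid location: nearest slice for vertebral/disc
    landmarks, linear interpolation between slice centers for caudal points."""
    pos = _location_position_mm(label, geometry, grid)
    w = np.zeros(centers_mm.size)
    if grid.index(label) >= grid.n_caudal:  # vertebral/disc: nearest slice
        dz = centers_mm[1] - centers_mm[0]
        i = int(np.clip(round(pos / dz - 0.5), 0, centers_mm.size - 1))
        w[i] = 1.0
    else:  # caudal point: linear interpolation
        j = int(np.clip(np.searchsorted(centers_mm, pos) - 1,
                        0, centers_mm.size - 2))
        frac = (pos - centers_mm[j]) / (centers_mm[j + 1] - centers_mm[j])
        frac = float(np.clip(frac, 0.0, 1.0))
        w[j] = 1.0 - frac
        w[j + 1] = frac
    return w


def _solve_age_gradient(z: np.ndarray, f0: np.ndarray, w: np.ndarray,
                        s: float) -> np.ndarray:
    """Relative age tilt r(z) whose normalized crossing sits exactly on the
    planted readout.

    Normalized age curves cross where the local relative tilt equals its
    f0-weighted mean, so the pivot ``z0`` of the hinge
    ``r(z) = s * max(z - z0, 0)`` (or its caudal mirror
    ``-s * max(z0 - z, 0)``) is solved such that the readout functional
    ``w`` (nearest slice or linear interpolation, exactly as the
    standardization reads the location) satisfies
    ``(w @ (f0 r)) / (w @ f0) = sum(f0 r) / sum(f0)``.  The hinge is flat on
    one side and strictly linear on the other, so it crosses its own mean
    level exactly once: the planted location is the unique crossing.  The
    orientation is chosen by the side of the f0 centroid the readout falls
    on (cranial hinge for locations above it, caudal mirror below).
    """
    from scipy.optimize import brentq

    wf0 = w @ f0
    sf0 = f0.sum()
    cranial = (w @ z) / np.sum(w) >= (f0 @ z) / sf0

    def tilt(z0: float) -> np.ndarray:
        # unit slope; the balance condition is linear in the slope, so the
        # pivot does not depend on it
        if cranial:
            return np.maximum(z - z0, 0.0)
        return -np.maximum(z0 - z, 0.0)

    def balance(z0: float) -> float:
        r = tilt(z0)
        return (w @ (f0 * r)) / wf0 - (f0 @ r) / sf0

    scan = np.linspace(z[0] - 2 * (z[-1] - z[0]), z[-1], 257) if cranial \
        else np.linspace(z[0], z[-1] + 2 * (z[-1] - z[0]), 257)
    vals = np.array([balance(z0) for z0 in scan])
    sign = np.sign(vals)
    nz = sign != 0
    idx = np.nonzero(np.diff(sign[nz]) != 0)[0]
    if idx.size == 0:
        raise ValueError(
            "cannot pivot the age gradient at the planted location for "
            "this geometry")
    pos = np.nonzero(nz)[0]
    a, b = scan[pos[idx[0]]], scan[pos[idx[0] + 1]]
    hinge = tilt(float(brentq(balance, a, b, xtol=1e-12)))
    # scale the slope so the f0-weighted mean absolute relative contrast is
    # |s| per decade (tail pivots get steeper slopes, otherwise the bulk of
    # the profile would carry almost no age contrast), bounded so that
    # 1 + delta*r stays positive over the 20-73 year age range
    level = (f0 @ hinge) / sf0
    mad = (f0 @ np.abs(hinge - level)) / sf0
    delta_max = 2.8
    mag = min(abs(s) / max(mad, 1e-9),
              0.9 / (delta_max * float(np.abs(hinge).max())))
    return np.sign(s) * mag * hinge


def generate_true_profile(
    record,
    geometry: SpineLandmarks,
    model: ProfileModel,
    seed: int,
    grid: AnatomicalGrid = DEFAULT_GRID,
    slice_thickness_cm: float = 0.3,
) -> SliceProfile:
    """Continuous per-slice VAT areas for one participant.

    The density on the slice grid is ``f = f0 + delta * g`` with ``f0`` the
    pelvic + abdominal mixture, ``delta`` the participant's age in decades
    relative to the model reference, and ``g`` a zero-sum tilt whose
    coefficients are solved so the standardized readout at the planted
    location is exactly age-independent.  Slice areas scale the normalized
    density by the participant's ground-truth VAT volume, so the sum of
    area x thickness equals ``vat_total_l`` exactly.
    """
    rng = np.random.default_rng(seed)
    age = float(record["age"])
    vat_ml = float(record["vat_total_l"]) * 1000.0

    top = trunk_extent_mm(geometry)
    dz = slice_thickness_cm * 10.0
    nz = int(np.ceil(top / dz))
    centers = (np.arange(nz) + 0.5) * dz  # mm
    z = centers / 10.0                    # cm

    p_w = model.pelvic_plateau
    a_w = model.abdominal_peak_height
    if model.shape_jitter > 0:
        p_w = p_w * rng.lognormal(0.0, model.shape_jitter)
        a_w = a_w * rng.lognormal(0.0, model.shape_jitter)

    fh = geometry["FH"] / 10.0
    l5 = geometry["L5"] / 10.0
    boundary = l5 - model.boundary_offset_cm
    mu_p = 0.5 * (fh + boundary)
    sigma_p = max((boundary - fh) / model.pelvic_width_factor, 0.5)
    mu_a = _location_position_mm(model.abdominal_peak_location,
                                 geometry, grid) / 10.0
    sigma_a = model.abdominal_sigma_cm

    P = p_w * np.exp(-0.5 * ((z - mu_p) / sigma_p) ** 2)
    sig_a = np.where(z < mu_a, sigma_a, model.abdominal_sigma_up_cm)
    A = a_w * np.exp(-0.5 * ((z - mu_a) / sig_a) ** 2)
    f0 = P + A
    delta = (age - model.age_ref_years) / 10.0
    c1 = model.age_slope_pelvic

    if model.planted_intersection is not None and model.age_slope_abdominal is None:
        # hinge age gradient with mean relative contrast |age_slope_pelvic|
        # per decade; negative slope: age shifts VAT share cranially
        w = _readout_weights(model.planted_intersection, geometry, grid,
                             centers)
        r = _solve_age_gradient(z, f0, w, -c1)
        f = f0 * (1.0 + delta * r)
    else:
        c_a = model.age_slope_abdominal or 0.0
        f = f0 + delta * (c1 * P + c_a * A)
    if model.noise_sd > 0:
        f = f + rng.normal(0.0, model.noise_sd, nz)
    f = np.maximum(f, 0.0)
    total = f.sum()
    if total <= 0:
        raise ValueError("degenerate profile: density vanished everywhere")
    areas = vat_ml * (f / total) / slice_thickness_cm
    return SliceProfile(areas_cm2=areas, slice_thickness_cm=slice_thickness_cm)


def render_mask(
    areas: SliceProfile | np.ndarray,
    geometry: SpineLandmarks,
    voxel_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    seed: int = 0,
    axis_ratio: float = 1.5,
    max_fov_mm: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize per-slice areas into a binary VAT volume plus spine labels.

    Each slice holds a single filled ellipse whose voxel count matches the
    requested area to within half a voxel (per-slice area is the only
    quantity consumed downstream, so organ-level realism is not attempted).
    Spine labels are small blobs at the landmark positions, ids as in
    :data:`vatslice.landmarks.LANDMARK_IDS`.
    """
    if isinstance(areas, SliceProfile):
        prof = areas
        if abs(prof.slice_thickness_cm * 10.0 - voxel_spacing_mm[2]) > 1e-9:
            raise ValueError("slice thickness of profile and spacing differ")
        areas_cm2 = prof.areas_cm2
    else:
        areas_cm2 = np.asarray(areas, dtype=float)
    if not np.all(np.isfinite(areas_cm2)) or np.any(areas_cm2 < 0):
        raise ValueError("areas must be finite and non-negative")
    dx, dy, dz = (float(s) for s in voxel_spacing_mm)
    if min(dx, dy, dz) <= 0:
        raise ValueError("voxel spacing must be positive")
    rng = np.random.default_rng(seed)

    voxel_area = dx * dy / 100.0  # cm²
    max_area = float(areas_cm2.max(initial=0.0))
    # semi-major axis of the largest ellipse plus 2 cm margin
    r_cm = np.sqrt(max(max_area, voxel_area) * axis_ratio / np.pi) + 2.0
    if 2 * r_cm * 10.0 > max_fov_mm:
        raise ValueError(
            f"requested area {max_area:.0f} cm² exceeds the "
            f"{max_fov_mm:.0f} mm slice field of view")
    nx = int(np.ceil(2 * r_cm * 10.0 / dx)) | 1  # odd -> centred
    ny = int(np.ceil(2 * r_cm * 10.0 / dy)) | 1
    nz = areas_cm2.size

    cx = (nx // 2 + rng.uniform(-2.0, 2.0)) * dx
    cy = (ny // 2 + rng.uniform(-2.0, 2.0)) * dy
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    # elliptical squared radius; sort voxels once, fill k nearest per slice
    r2 = ((xs[:, None] - cx) / axis_ratio) ** 2 + (ys[None, :] - cy) ** 2
    order = np.argsort(r2, axis=None)

    vat = np.zeros((nx, ny, nz), dtype=np.uint8)
    flat_len = nx * ny
    for i, area in enumerate(areas_cm2):
        k = int(round(area / voxel_area))
        if k:
            sl = np.zeros(flat_len, dtype=np.uint8)
            sl[order[:k]] = 1
            vat[:, :, i] = sl.reshape(nx, ny)

    spine = np.zeros_like(vat)
    for lid, lab in LANDMARK_IDS.items():
        zi = int(np.clip(round(geometry[lab] / dz - 0.5), 0, nz - 1))
        spine[nx // 2 - 1: nx // 2 + 2, ny // 2 - 1: ny // 2 + 2, zi] = lid
    return vat, spine


def _grid_strata(df: pd.DataFrame) -> pd.Series:
    """(sex, bmi_group, age_group) per row; NaN groups for out-of-range."""
    from .cohort import bmi_group_of, age_group_of

    def key(row):
        try:
            return (row["sex"], bmi_group_of(row["bmi"]),
                    age_group_of(row["age"]))
        except ValueError:
            return None

    return df.apply(key, axis=1)


def inject_exclusions(
    cohort: pd.DataFrame,
    counts: dict[str, int],
    seed: int,
    min_subgroup: int = 10,
) -> pd.DataFrame:
    """Plant exclusion structure into a cohort, returning a modified copy.

    ``counts`` may contain ``fat_water_swap``, ``corrupted``,
    ``missing_anthropometry`` (flags set on disjoint participants),
    ``underweight`` (BMI forced below 18.5) and ``small_stratum``
    (participants moved into otherwise-empty sex x BMI x age strata in
    batches of at most ``min_subgroup - 1``).  Strata that are naturally
    small are first repaired by reassigning their members' ages, so that
    downstream exclusion counts match the request exactly.
    """
    unknown = set(counts) - set(EXCLUSION_FLAGS) - {"underweight",
                                                    "small_stratum"}
    if unknown:
        raise ValueError(f"unknown exclusion keys {unknown}")
    if sum(counts.values()) > len(cohort):
        raise ValueError("requested exclusions exceed cohort size")
    df = cohort.copy(deep=True)
    rng = np.random.default_rng(seed)

    flagged = np.zeros(len(df), dtype=bool)
    for flag in EXCLUSION_FLAGS:
        k = int(counts.get(flag, 0))
        if k == 0:
            continue
        pool = np.nonzero(~flagged)[0]
        pick = rng.choice(pool, size=k, replace=False)
        df.iloc[pick, df.columns.get_loc(f"flag_{flag}")] = True
        flagged[pick] = True

    k_uw = int(counts.get("underweight", 0))
    if k_uw:
        pool = np.nonzero(~flagged)[0]
        pick = rng.choice(pool, size=k_uw, replace=False)
        h = df.iloc[pick]["height_cm"].to_numpy()
        new_bmi = rng.uniform(16.5, 18.4, k_uw)
        df.iloc[pick, df.columns.get_loc("bmi")] = new_bmi
        df.iloc[pick, df.columns.get_loc("weight_kg")] = np.round(
            new_bmi * (h / 100.0) ** 2, 2)
        flagged[pick] = True

    k_small = int(counts.get("small_stratum", 0))
    if k_small:
        df = _plant_small_strata(df, flagged, k_small, rng, min_subgroup)
    return df


def _plant_small_strata(df: pd.DataFrame, flagged: np.ndarray, k: int,
                        rng: np.random.Generator,
                        min_subgroup: int) -> pd.DataFrame:
    eligible = ~flagged & (df["bmi"].to_numpy() >= 18.5)
    strata = _grid_strata(df)
    strata[~eligible] = None

    # repair naturally small strata: move members into the largest age
    # group of the same sex x BMI group (falling back to the largest
    # stratum of the same sex) so they survive the size filter and the
    # planted counts stay exact
    sizes = strata.value_counts()
    for key in list(sizes.index):
        if sizes[key] >= min_subgroup:
            continue
        s, g, _ = key
        peers = {k: n for k, n in sizes.items()
                 if k[0] == s and k[1] == g and n >= min_subgroup}
        if not peers:
            peers = {k: n for k, n in sizes.items()
                     if k[0] == s and n >= min_subgroup}
        if not peers:
            raise ValueError(f"cannot repair small stratum {key}: no "
                             f"receiving stratum of size >= {min_subgroup}")
        target = max(peers, key=peers.get)
        rows = strata[strata == key].index
        lo, hi = AGE_GROUP_BOUNDS[target[2]]
        df.loc[rows, "age"] = rng.integers(lo, hi, rows.size)
        if target[1] != g:
            lo_b, hi_b = BMI_GROUP_BOUNDS[target[1]]
            mid = 0.5 * (lo_b + hi_b)
            df.loc[rows, "bmi"] = mid
            h = df.loc[rows, "height_cm"].to_numpy()
            df.loc[rows, "weight_kg"] = np.round(mid * (h / 100.0) ** 2, 2)
        for row in rows:
            strata.at[row] = target
        sizes[target] += rows.size
        sizes[key] = 0

    sizes = strata.value_counts()
    all_keys = [(s, g, a) for s in SEXES for g in BMI_GROUPS
                for a in AGE_GROUPS]
    empty = [key for key in all_keys if sizes.get(key, 0) == 0]
    batch = min_subgroup - 1
    n_batches = int(np.ceil(k / batch))
    if len(empty) < n_batches:
        raise ValueError("not enough empty strata to plant "
                         f"{k} small-stratum members")

    donor_key = sizes.idxmax()
    donors = strata[strata == donor_key].index.to_numpy()
    pick = rng.choice(donors, size=k, replace=False)
    for b in range(n_batches):
        members = pick[b * batch:(b + 1) * batch]
        s, g, a = empty[b]
        lo_a, hi_a = AGE_GROUP_BOUNDS[a]
        lo_b, hi_b = BMI_GROUP_BOUNDS[g]
        mid_bmi = 0.5 * (lo_b + hi_b)
        df.loc[members, "sex"] = s
        df.loc[members, "age"] = rng.integers(lo_a, hi_a, members.size)
        df.loc[members, "bmi"] = mid_bmi
        h = df.loc[members, "height_cm"].to_numpy()
        df.loc[members, "weight_kg"] = np.round(mid_bmi * (h / 100.0) ** 2, 2)
    return df


def generate_cohort_profiles(
    cohort: pd.DataFrame,
    seed: int,
    models: dict[tuple[str, str], ProfileModel] | None = None,
    grid: AnatomicalGrid = DEFAULT_GRID,
    slice_thickness_cm: float = 0.3,
    geometry_kwargs: dict | None = None,
) -> tuple[dict[str, SliceProfile], dict[str, SpineLandmarks]]:
    """Geometries and slice profiles for every participant of a cohort.

    Per-participant seeds are spawned from ``seed`` so the output is
    reproducible and independent of cohort ordering.
    """
    from .cohort import bmi_group_of

    models = models or default_profile_models()
    geometry_kwargs = geometry_kwargs or {}
    profiles: dict[str, SliceProfile] = {}
    geometries: dict[str, SpineLandmarks] = {}
    for i, (_, rec) in enumerate(cohort.iterrows()):
        geo_seed, prof_seed = np.random.SeedSequence([seed, i]).generate_state(2)
        geometry = generate_geometry(rec, int(geo_seed) % (2 ** 31),
                                     **geometry_kwargs)
        model = models[(rec["sex"], bmi_group_of(rec["bmi"]))]
        prof = generate_true_profile(rec, geometry, model,
                                     int(prof_seed) % (2 ** 31), grid,
                                     slice_thickness_cm)
        profiles[rec["id"]] = prof
        geometries[rec["id"]] = geometry
    return profiles, geometries
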