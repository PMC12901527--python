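"""Cohort stratification, exclusions, stratum profiles, reference-slice
search and scaling-factor derivation.

BMI groups use the half-open intervals [18.5,25), [25,30), [30,35),
[35,40), [40,inf) kg/m²; age groups [20,30), [30,40), [40,50), [50,60),
[60,inf) years — individuals older than 70 are subsumed into the oldest
group, and underweight participants (BMI < 18.5) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

BMI_EDGES = (18.5, 25.0, 30.0, 35.0, 40.0)
BMI_LABELS = ("I", "II", "III", "IV", "V")
AGE_EDGES = (20, 30, 40, 50, 60)
AGE_LABELS = ("i", "ii", "iii", "iv", "v")


class ExclusionError(ValueError):
    """Raised when a participant falls outside the analyzable ranges."""


def bmi_group_of(bmi: float) -> str:
    if not np.isfinite(bmi):
        raise ExclusionError("missing BMI")
    if bmi < BMI_EDGES[0]:
        raise ExclusionError(
            f"underweight participant (BMI {bmi:.1f} < 18.5 kg/m²) excluded")
    idx = int(np.searchsorted(BMI_EDGES, bmi, side="right")) - 1
    return BMI_LABELS[idx]


def age_group_of(age: float) -> str:
    if not np.isfinite(age):
        raise ExclusionError("missing age")
    if age < AGE_EDGES[0]:
        raise ExclusionError(f"age {age} below study range (>= 20 years)")
    idx = int(np.searchsorted(AGE_EDGES, age, side="right")) - 1
    return AGE_LABELS[idx]


@dataclass(frozen=True)
class GroupAssignment:
    sex: str
    bmi_group: str
    age_group: str


def assign_groups(record) -> GroupAssignment:
    """Deterministic sex x BMI x age group assignment for one participant."""
    return GroupAssignment(
        sex=str(record["sex"]),
        bmi_group=bmi_group_of(float(record["bmi"])),
        age_group=age_group_of(float(record["age"])),
    )


def assign_groups_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group columns for a cohort that already satisfies the inclusion
    ranges (BMI >= 18.5, age >= 20); raises otherwise."""
    if (cohort["bmi"] < BMI_EDGES[0]).any():
        raise ExclusionError("cohort contains underweight participants; "
                             "run apply_exclusions first")
    if (cohort["age"] < AGE_EDGES[0]).any():
        raise ExclusionError("cohort contains participants below the study "
                             "age range; run apply_exclusions first")
    out = cohort[["id", "sex"]].copy()
    out["bmi_group"] = pd.cut(
        cohort["bmi"], list(BMI_EDGES) + [np.inf], right=False,
        labels=BMI_LABELS).astype(str)
    out["age_group"] = pd.cut(
        cohort["age"], list(AGE_EDGES) + [np.inf], right=False,
        labels=AGE_LABELS).astype(str)
    return out.set_index("id")


def apply_exclusions(
    cohort: pd.DataFrame,
    min_subgroup: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the exclusion cascade and report per-criterion counts.

    Removal order: fat-water swap -> corrupted image data -> missing
    anthropometry -> underweight (BMI < 18.5 kg/m²) -> sex x BMI x age
    strata with fewer than ``min_subgroup`` members.  Total removals are
    conserved: ``len(in) - len(out) == sum(counts.values())``.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    df = cohort
    counts: dict[str, int] = {}
    for flag in ("fat_water_swap", "corrupted", "missing_anthropometry"):
        col = f"flag_{flag}"
        sel = df[col].astype(bool) if col in df else pd.Series(False,
                                                               index=df.index)
        counts[flag] = int(sel.sum())
        df = df[~sel]

    underweight = df["bmi"] < BMI_EDGES[0]
    counts["underweight"] = int(underweight.sum())
    df = df[~underweight]

    groups = assign_groups_frame(df)
    sizes = groups.groupby(["sex", "bmi_group", "age_group"],
                           observed=True).size()
    small = sizes[sizes < min_subgroup]
    keys = pd.MultiIndex.from_frame(
        groups[["sex", "bmi_group", "age_group"]].reset_index(drop=True))
    in_small = pd.Series(keys.isin(small.index), index=df.index)
    counts["small_stratum"] = int(in_small.sum())
    df = df[~in_small.to_numpy()]
    return df.copy(), counts


def stratum_profiles(
    profiles: pd.DataFrame,
    groups: pd.DataFrame,
) -> pd.DataFrame:
    """Per-location mean and SEM of the standardized profiles in every
    sex x BMI x age stratum.

    ``profiles``: matrix indexed by id with grid-location columns (percent
    of total VAT) and optionally ``vat_total_l`` (ignored here).
    ``groups``: frame indexed by id with sex, bmi_group, age_group.
    Returns a long frame [sex, bmi_group, age_group, location, n, mean_pct,
    sem_pct] with locations in grid order.
    """
    loc_cols = [c for c in profiles.columns if c != "vat_total_l"]
    missing = profiles.index.difference(groups.index)
    if len(missing):
        raise ValueError(f"profiles without group assignment: "
                         f"{list(missing[:5])}")
    joined = profiles[loc_cols].join(
        groups[["sex", "bmi_group", "age_group"]], how="left")
    rows = []
    for (sex, bg, ag), sub in joined.groupby(
            ["sex", "bmi_group", "age_group"], observed=True):
        vals = sub[loc_cols]
        n = len(vals)
        if n == 0:  # pragma: no cover - groupby omits empty strata
            warnings.warn(f"empty stratum {(sex, bg, ag)} omitted")
            continue
        mean = vals.mean(axis=0)
        sem = vals.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else \
            pd.Series(0.0, index=loc_cols)
        for loc in loc_cols:
            rows.append({"sex": sex, "bmi_group": bg, "age_group": ag,
                         "location": loc, "n": n,
                         "mean_pct": float(mean[loc]),
                         "sem_pct": float(sem[loc])})
    return pd.DataFrame(rows)


def find_intersection(
    stats: pd.DataFrame,
    sex: str,
    bmi_group: str,
    spread_metric: str = "range",
    min_level_frac: float = 0.1,
) -> str:
    """Grid location where the age-group mean profiles of one sex x BMI
    stratum differ least (the age-independent reference slice).

    The spread at each location is the range (max - min) of the age-group
    means by default; ``spread_metric="variance"`` uses their variance.
    The search is restricted to locations whose pooled mean percentage is
    at least ``min_level_frac`` times the profile maximum: a slice with
    (near-)zero VAT has trivially zero age spread but carries no signal for
    volume estimation.  Ties are broken toward the location with the
    largest pooled mean percentage.  Raises if fewer than two age groups
    are present.
    """
    sub = stats[(stats["sex"] == sex) & (stats["bmi_group"] == bmi_group)]
    if sub.empty:
        raise ValueError(f"no strata for sex={sex}, bmi_group={bmi_group}")
    locations = list(dict.fromkeys(sub["location"]))  # preserve grid order
    pivot = sub.pivot(index="location", columns="age_group",
                      values="mean_pct").loc[locations]
    if pivot.shape[1] < 2:
        raise ValueError(
            "intersection undefined: need at least two age groups, got "
            f"{pivot.shape[1]}")
    ns = sub.pivot(index="location", columns="age_group",
                   values="n").loc[locations]
    pooled = (pivot * ns).sum(axis=1) / ns.sum(axis=1)
    admissible = pooled >= min_level_frac * pooled.max()

    if spread_metric == "range":
        spread = pivot.max(axis=1) - pivot.min(axis=1)
    elif spread_metric == "variance":
        spread = pivot.var(axis=1, ddof=0)
    else:
        raise ValueError(f"unknown spread metric {spread_metric!r}")
    spread = spread[admissible]

    smin = spread.min()
    ties = spread.index[spread <= smin + 1e-12 * max(smin, 1e-30)]
    if len(ties) == 1:
        return str(ties[0])
    return str(pooled.loc[ties].idxmax())


def slice_area_at(
    profiles: pd.DataFrame,
    location: str,
    slice_thickness_cm: float = 0.3,
) -> pd.Series:
    """Cross-sectional VAT area (cm²) at one grid location, recovered from
    the standardized percentage and the reference volume:
    area = pct/100 * V[cm³] / thickness."""
    if location not in profiles.columns:
        raise ValueError(f"location {location!r} not in profile matrix")
    if "vat_total_l" not in profiles.columns:
        raise ValueError("profile matrix misses vat_total_l")
    return (profiles[location] / 100.0 * profiles["vat_total_l"] * 1000.0
            / slice_thickness_cm)


def derive_factor(
    profiles: pd.DataFrame,
    groups: pd.DataFrame,
    location: str,
    sex: str,
    bmi_group: str,
    slice_thickness_cm: float = 0.3,
    method: str = "ratio_of_means",
) -> float:
    """Scaling factor f such that V̂[l] = area[cm²] * f / 1000.

    Default is the ratio of group means, f = 1000 * mean(V[l]) /
    mean(area[cm²]), pooled over all age groups of the sex x BMI group —
    equivalently the slice thickness divided by the (area-weighted) mean
    per-slice VAT fraction at the location.  ``method="mean_of_ratios"``
    averages per-participant factors instead (kept for sensitivity checks).
    """
    sel = groups[(groups["sex"] == sex) & (groups["bmi_group"] == bmi_group)]
    if sel.empty:
        raise ValueError(f"empty stratum sex={sex}, bmi_group={bmi_group}")
    sub = profiles.loc[profiles.index.intersection(sel.index)]
    areas = slice_area_at(sub, location, slice_thickness_cm)
    if method == "ratio_of_means":
        mean_area = float(areas.mean())
        if mean_area <= 0:
            raise ValueError(f"zero mean area at {location!r}")
        return 1000.0 * float(sub["vat_total_l"].mean()) / mean_area
    if method == "mean_of_ratios":
        if (areas <= 0).any():
            raise ValueError(f"zero area at {location!r} for some "
                             "participants")
        return float((1000.0 * sub["vat_total_l"] / areas).mean())
    raise ValueError(f"unknown factor method {method!r}")


def build_factor_table(
    profiles: pd.DataFrame,
    groups: pd.DataFrame,
    slice_thickness_cm: float = 0.3,
    spread_metric: str = "range",
    factor_method: str = "ratio_of_means",
) -> pd.DataFrame:
    """Reference location and scaling factor for every sex x BMI group
    present: the location minimizing the age spread, then the pooled
    factor at that location."""
    stats = stratum_profiles(profiles, groups)
    rows = []
    for (sex, bg), _ in stats.groupby(["sex", "bmi_group"], observed=True):
        try:
            loc = find_intersection(stats, sex, bg, spread_metric)
        except ValueError as exc:
            warnings.warn(f"sex={sex} bmi_group={bg}: {exc}; group skipped")
            continue
        f = derive_factor(profiles, groups, loc, sex, bg,
                          slice_thickness_cm, factor_method)
        rows.append({"sex": sex, "bmi_group": bg, "location": loc,
                     "factor": f})
    return pd.DataFrame(rows)


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def two_sample_t(a, b) -> TTestResult:
    """Pooled-variance two-sample t-test with df = n1 + n2 - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        return TTestResult(0.0, df, 1.0)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), float(p))


def kde_distance(
    distances,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate (Silverman bandwidth) of measured
    femoral-head-to-L5 distances, evaluated on ``grid`` (cm)."""
    d = np.asarray(distances, dtype=float)
    if d.size < 2 or np.unique(d).size < 2:
        raise ValueError("need at least two distinct distances "
                         "(constant input gives zero bandwidth)")
    kde = sps.gaussian_kde(d, bw_method="silverman")
    if grid is None:
        bw = kde.factor * d.std(ddof=1)
        grid = np.linspace(d.min() - 3 * bw, d.max() + 3 * bw, n_grid)
    return grid, kde(grid)
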