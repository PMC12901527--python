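"""Single-slice VAT volume estimation and its validation.

The estimator is V̂[l] = A[cm²] * f / 1000 with A the VAT cross-sectional
area at the sex- and BMI-specific reference slice and f the corresponding
scaling factor (the reciprocal of the mean single-slice VAT fraction,
expressed per liter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def estimate_vat(area_cm2, factor) -> np.ndarray | float:
    """Estimated total VAT volume in liters from a single-slice area.

    Homogeneous of degree one in the area; rejects negative areas and
    non-positive factors.
    """
    area = np.asarray(area_cm2, dtype=float)
    f = np.asarray(factor, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be >= 0")
    if np.any(f <= 0):
        raise ValueError("factor must be > 0")
    out = area * f / 1000.0
    return float(out) if out.ndim == 0 else out


def _as_group_frame(groups: pd.DataFrame | None, index) -> pd.DataFrame:
    if groups is None:
        return pd.DataFrame({"sex": ["all"] * len(index)}, index=index)
    return groups


def validate_correlation(
    estimates: pd.Series,
    references: pd.Series,
    groups: pd.DataFrame | None = None,
    by: tuple[str, ...] = ("sex", "bmi_group"),
) -> pd.DataFrame:
    """Pearson correlation and least-squares line per group.

    Regression is reported in both orientations (reference on estimate and
    estimate on reference).  Groups with zero variance in either variable
    get NaN statistics and ``degenerate=True``.
    """
    est, ref = estimates.align(references, join="inner")
    g = _as_group_frame(groups, est.index).loc[est.index]
    by = tuple(c for c in by if c in g.columns)
    rows = []
    for key, sub in g.groupby(list(by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        e = est.loc[sub.index].to_numpy()
        r = ref.loc[sub.index].to_numpy()
        row = dict(zip(by, key))
        row["n"] = e.size
        if e.size < 3 or np.var(e) == 0 or np.var(r) == 0:
            row.update(pearson_r=np.nan, slope=np.nan, intercept=np.nan,
                       slope_rev=np.nan, intercept_rev=np.nan,
                       degenerate=True)
        else:
            pr = sps.pearsonr(e, r).statistic
            fit = sps.linregress(e, r)
            rev = sps.linregress(r, e)
            row.update(pearson_r=float(pr), slope=float(fit.slope),
                       intercept=float(fit.intercept),
                       slope_rev=float(rev.slope),
                       intercept_rev=float(rev.intercept),
                       degenerate=False)
        rows.append(row)
    return pd.DataFrame(rows)


def _boxplot_stats(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_lo": float(inliers.min()), "whisker_hi": float(inliers.max()),
        "n_outliers": int(((x < lo_fence) | (x > hi_fence)).sum()),
    }


def error_metrics(
    estimates: pd.Series,
    references: pd.Series,
    groups: pd.DataFrame | None = None,
    by: tuple[str, ...] = ("sex",),
    relative_definition: str = "of_mean_error",
) -> pd.DataFrame:
    """Signed-error summaries per group.

    Signed error = estimate - reference (liters).  The relative mean
    absolute error is |mean signed error| / mean reference * 100 by
    default; ``relative_definition="of_abs_errors"`` uses
    mean(|error|) / mean reference * 100 instead.  Boxplot statistics use
    the 1.5 x IQR whisker convention.
    """
    est, ref = estimates.align(references, join="inner")
    err = est - ref
    g = _as_group_frame(groups, est.index).loc[est.index]
    by = tuple(c for c in by if c in g.columns)
    rows = []
    for key, sub in g.groupby(list(by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        e = err.loc[sub.index].to_numpy()
        r = ref.loc[sub.index].to_numpy()
        if e.size < 2:
            raise ValueError(f"group {key} has fewer than two pairs")
        row = dict(zip(by, key))
        row["n"] = e.size
        row["mean_error_l"] = float(e.mean())
        row["sd_error_l"] = float(e.std(ddof=1))
        mean_ref = float(r.mean())
        if mean_ref == 0:
            row["rmae_pct"] = np.nan
            row["rmae_undefined"] = True
        else:
            if relative_definition == "of_mean_error":
                row["rmae_pct"] = abs(e.mean()) / mean_ref * 100.0
            elif relative_definition == "of_abs_errors":
                row["rmae_pct"] = float(np.abs(e).mean()) / mean_ref * 100.0
            else:
                raise ValueError(
                    f"unknown relative_definition {relative_definition!r}")
            row["rmae_undefined"] = False
        row.update(_boxplot_stats(e))
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_cohort(
    profiles: pd.DataFrame,
    groups: pd.DataFrame,
    factor_table: pd.DataFrame,
    slice_thickness_cm: float = 0.3,
) -> pd.DataFrame:
    """Apply the factor table to every participant.

    Reads the single-slice area at each group's reference location from the
    standardized profile matrix and returns a frame indexed by id with
    estimated_l, reference_l and error_l.
    """
    from .cohort import slice_area_at

    rows = []
    for _, frow in factor_table.iterrows():
        sel = groups[(groups["sex"] == frow["sex"])
                     & (groups["bmi_group"] == frow["bmi_group"])]
        sub = profiles.loc[profiles.index.intersection(sel.index)]
        if sub.empty:
            continue
        area = slice_area_at(sub, frow["location"], slice_thickness_cm)
        est = estimate_vat(area.to_numpy(), frow["factor"])
        rows.append(pd.DataFrame({
            "estimated_l": est,
            "reference_l": sub["vat_total_l"].to_numpy(),
        }, index=sub.index))
    if not rows:
        raise ValueError("factor table matches no participants")
    out = pd.concat(rows)
    out["error_l"] = out["estimated_l"] - out["reference_l"]
    out.index.name = "id"
    return out.sort_index()
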