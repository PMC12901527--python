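"""File handling: NIfTI volumes, manifest-stamped CSV, factor-table JSON.

CSV dialect: UTF-8, comma separator, "." decimal, mandatory header row.
Every file written by a pipeline stage starts with a comment line
identifying the producing stage and the configuration hash, so outputs are
traceable without being byte-fragile (no timestamps).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(volume: np.ndarray, spacing_mm, path) -> None:
    """Write a volume with the voxel spacing recorded in the header."""
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing_mm))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a volume and its voxel spacing (dx, dy, dz) in mm."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    # zooms are stored as float32; round off the representation error
    return data, tuple(round(float(z), 6) for z in zooms)


def write_csv(df: pd.DataFrame, path, stage: str, config_hash: str,
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# vatslice stage={stage} config={config_hash}\n")
        df.to_csv(fh, index=index)


def read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def write_factor_json(factor_table: pd.DataFrame, path, stage: str,
                      config_hash: str) -> None:
    """Factor table as JSON: sex -> bmi_group -> {location, factor}."""
    payload: dict = {"_stage": stage, "_config": config_hash}
    for _, row in factor_table.iterrows():
        payload.setdefault(row["sex"], {})[row["bmi_group"]] = {
            "location": row["location"], "factor": float(row["factor"]),
        }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_factor_json(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    rows = []
    for sex, groups in payload.items():
        if sex.startswith("_"):
            continue
        for bg, entry in groups.items():
            rows.append({"sex": sex, "bmi_group": bg,
                         "location": entry["location"],
                         "factor": entry["factor"]})
    return pd.DataFrame(rows)


def write_manifest(path, stage: str, config_hash: str, extra: dict | None = None) -> None:
    from . import __version__

    payload = {"stage": stage, "config": config_hash,
               "vatslice_version": __version__}
    payload.update(extra or {})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def landmarks_frame(geometries: dict) -> pd.DataFrame:
    """Long landmark table (id, label, position_mm) for a cohort."""
    return pd.concat(
        [geo.to_frame(pid) for pid, geo in geometries.items()],
        ignore_index=True,
    )
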