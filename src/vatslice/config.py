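"""Run configuration for the command-line pipeline.

A config is a flat YAML mapping; unknown keys are rejected and numeric
parameters are range-checked.  All randomness flows from the single
``seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 500
    outdir: str = "vatslice_out"

    # synthetic-study conditions
    noise_sd: float = 0.0025
    shape_jitter: float = 0.25
    exclusion_counts: dict = field(default_factory=dict)

    # grid / acquisition geometry
    n_caudal_points: int = 26
    slice_thickness_cm: float = 0.3
    voxel_spacing_mm: tuple = (1.4, 1.4, 3.0)
    write_masks: int = 5  # participants also rendered as NIfTI volumes

    # alternative-definition toggles
    spread_metric: str = "range"            # or "variance"
    factor_method: str = "ratio_of_means"   # or "mean_of_ratios"
    relative_error: str = "of_mean_error"   # or "of_abs_errors"

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_caudal_points < 2:
            raise ValueError("n_caudal_points must be >= 2")
        if self.slice_thickness_cm <= 0:
            raise ValueError("slice_thickness_cm must be positive")
        if self.noise_sd < 0 or self.shape_jitter < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.write_masks < 0:
            raise ValueError("write_masks must be >= 0")
        if len(self.voxel_spacing_mm) != 3 or min(self.voxel_spacing_mm) <= 0:
            raise ValueError("voxel_spacing_mm must be three positive values")
        if self.spread_metric not in ("range", "variance"):
            raise ValueError(f"unknown spread_metric {self.spread_metric!r}")
        if self.factor_method not in ("ratio_of_means", "mean_of_ratios"):
            raise ValueError(f"unknown factor_method {self.factor_method!r}")
        if self.relative_error not in ("of_mean_error", "of_abs_errors"):
            raise ValueError(f"unknown relative_error {self.relative_error!r}")
        self.voxel_spacing_mm = tuple(float(v) for v in self.voxel_spacing_mm)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so runs into
        different directories with the same settings match)."""
        payload = asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def outpath(self, name: str) -> Path:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name
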