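"""File formats, configuration and provenance.

NIfTI-1 volumes go through nibabel (gzip transparent); beat times and
motion traces are headered CSV; results and QC are JSON with a
provenance block (tool version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cardiac import BeatRecord
from .clusters import InferenceConfig
from .connectivity import PreprocConfig
from .simulate import AutonomicSimConfig, BrainSimConfig, CohortSpec

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_beats_csv",
    "read_motion_csv",
    "PipelineConfig",
    "provenance_block",
    "write_json",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a NIfTI-1 file; returns ``(data, affine, voxel_sizes_mm)``."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    return data, img.affine, np.asarray(img.header.get_zooms()[:3])


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return path


def read_beats_csv(path: str | Path) -> BeatRecord:
    """Beat record from a 1-column (beat times, s) or 2-column
    (time + IBI ms) headered CSV."""
    table = pd.read_csv(path)
    if table.shape[1] == 1:
        return BeatRecord(beat_times_s=table.iloc[:, 0].to_numpy(dtype=float))
    times = table.iloc[:, 0].to_numpy(dtype=float)
    return BeatRecord(beat_times_s=times)


def read_motion_csv(path: str | Path) -> np.ndarray:
    table = pd.read_csv(path)
    if table.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns, found {table.shape[1]}")
    return table.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Top-level run configuration aggregating every stage's settings."""

    seed: int = 0
    output_dir: str = "cardioconn-out"
    log_level: str = "INFO"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    autonomic: AutonomicSimConfig = field(default_factory=AutonomicSimConfig)
    brain: BrainSimConfig = field(default_factory=BrainSimConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    cardiac_trim_s: float = 60.0
    cardiac_rel_thr: float = 0.30
    cardiac_abs_thr_ms: float = 250.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load and validate; unknown keys anywhere are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sub = {
            "cohort": CohortSpec,
            "autonomic": AutonomicSimConfig,
            "brain": BrainSimConfig,
            "preproc": PreprocConfig,
            "inference": InferenceConfig,
        }
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                klass = sub[key]
                sub_known = {f.name for f in fields(klass)}
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown keys in section {key!r}: {sorted(sub_unknown)}"
                    )
                for tup in ("grid_dims", "band_hz", "age_mean_sd", "group_labels"):
                    if tup in value and isinstance(value[tup], list):
                        value[tup] = tuple(value[tup])
                kwargs[key] = klass(**value)
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.cohort.validate()
        self.autonomic.validate()
        self.brain.validate()
        self.preproc.validate()
        self.inference.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["brain"]["grid_dims"] = list(d["brain"]["grid_dims"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def provenance_block(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    return {
        "tool": "cardioconn",
        "version": __version__,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config_hash": config.digest() if config else None,
    }


def write_json(path: str | Path, payload: dict, config: PipelineConfig | None = None) -> Path:
    path = Path(path)
    payload = {"provenance": provenance_block(config), **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
    return path
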