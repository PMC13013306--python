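"""File I/O and run configuration.

NIfTI masks in (spacing read from the header, orientation used as stored,
no reorientation or resampling), CSV cohort tables in and out, JSON/CSV
report writing, and a serializable run configuration for reproducible
pipeline runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort_stats import validate_cohort
from .fractal import VoxelMask

__all__ = ["RunConfig", "read_mask", "write_mask", "read_cohort", "write_cohort", "write_report"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; JSON round-trip identical."""

    max_box_size: int | None = None
    fit_max_fraction: float = 0.5
    linearity_threshold: float = 0.98
    chi2_expected_threshold: float = 8.0
    n_boot_auc: int = 2000
    n_boot_calibration: int = 1000
    seed: int = 0
    cutoff: float | None = None        # None: use the Youden-index cutoff
    cohort_n: int = 110
    prevalence: float = 48 / 110
    binarize_threshold: float = 0.5
    output_dir: str = "stasfd_out"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_mask(path, threshold: float = 0.5) -> VoxelMask:
    """Load a 3D NIfTI mask, binarize (> threshold), keep header spacing."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite voxel values in {path}")
    return VoxelMask(data > threshold, spacing=spacing, source_id=str(path))


def write_mask(mask: VoxelMask, path) -> None:
    """Write a mask as uint8 NIfTI with spacing in the header."""
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (comma-separated, UTF-8, '.' decimal)."""
    df = pd.read_csv(path)
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_report(results: dict, out_dir) -> list[Path]:
    """Write a dict of result objects to ``out_dir``.

    DataFrames become CSV files, everything else JSON; the file stem is the
    dict key.  Returns the written paths (sorted, deterministic).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for key in sorted(results):
        value = results[key]
        if isinstance(value, pd.DataFrame):
            p = out / f"{key}.csv"
            value.to_csv(p, index=False)
        else:
            p = out / f"{key}.json"
            p.write_text(json.dumps(value, indent=2, sort_keys=True, default=_jsonify))
        written.append(p)
    return written


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
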