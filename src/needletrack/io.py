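"""Volume and manifest I/O.

Volumes are NIfTI (`.nii` / `.nii.gz`) with the voxel pitch in the affine so
spacing survives round trips; manifests are CSV; configuration snapshots are
JSON. Array axis order (depth, x_US, y_US) is stored as-is.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom_sim import InsertionRecord, VolumeGrid, dataset_manifest

__all__ = [
    "save_volume",
    "load_volume",
    "write_dataset",
    "load_manifest",
]


def save_volume(path: str | Path, volume: np.ndarray, grid: VolumeGrid) -> None:
    affine = np.diag([grid.pitch, grid.pitch, grid.pitch, 1.0])
    affine[:3, 3] = [grid.depth_min, *grid.lateral_origin]
    img = nib.Nifti1Image(np.asarray(volume), affine)
    img.header.set_zooms((grid.pitch,) * 3)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    pitch = float(zooms[0])
    origin = img.affine[:3, 3]
    grid = VolumeGrid(
        shape=vol.shape, pitch=pitch, depth_min=float(origin[0]),
        lateral_origin=(float(origin[1]), float(origin[2])),
    )
    return vol, grid


def write_dataset(
    records: Sequence[InsertionRecord],
    out_dir: str | Path,
    grid: VolumeGrid,
    config_snapshot: dict | None = None,
    compress: bool = True,
) -> Path:
    """Write volumes (NIfTI), the per-frame manifest (CSV) and a config snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    for rec in records:
        rec_dir = out / rec.id
        rec_dir.mkdir(exist_ok=True)
        for k, f in enumerate(rec.frames):
            save_volume(rec_dir / f"frame_{k:03d}{ext}", f.volume, grid)
    manifest = dataset_manifest(records, pitch=grid.pitch)
    manifest.to_csv(out / "manifest.csv", index=False)
    if config_snapshot is not None:
        (out / "config.json").write_text(json.dumps(config_snapshot, indent=2, default=str))
    return out


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
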