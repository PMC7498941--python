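"""File formats: NIfTI-1 volumes with JSON sidecars, delimited tables.

Conventions, fixed for cross-run reproducibility: volumes use a diagonal
affine scaled by the voxel size with 0-based indices and x-fastest
linearization; motion tables are 6-column CSV (translations in mm, then
rotations in radians); template sets are 4D NIfTI with a JSON sidecar
naming the components.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from netthin.synth import BoldSeries, MotionParams, TemplateSet, TissueMaps

__all__ = [
    "save_bold",
    "load_bold",
    "save_templates",
    "load_templates",
    "save_motion",
    "load_motion",
    "save_tissues",
    "load_tissues",
]

MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_rad", "rot_y_rad", "rot_z_rad"]
TISSUE_ORDER = ["wm", "csf", "bone", "gm"]


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm] * 3 + [1.0])


def save_bold(series: BoldSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data, _affine(series.voxel_size_mm))
    img.header.set_zooms((series.voxel_size_mm,) * 3 + (series.tr,))
    nib.save(img, path)
    return path


def load_bold(path: str | Path) -> BoldSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return BoldSeries(np.asarray(img.dataobj, dtype=float), tr=float(zooms[3]),
                      voxel_size_mm=float(zooms[0]))


def save_templates(templates: TemplateSet, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(templates.maps, _affine(templates.voxel_size_mm)), path)
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({"components": templates.names,
                                   "voxel_size_mm": templates.voxel_size_mm}, indent=2))
    return path


def load_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return TemplateSet(np.asarray(img.dataobj, dtype=float), meta["components"],
                       float(meta.get("voxel_size_mm", 3.0)))


def save_motion(motion: MotionParams, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(motion.values, columns=MOTION_COLUMNS).to_csv(path, index=False)
    return path


def load_motion(path: str | Path) -> MotionParams:
    df = pd.read_csv(path)
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion CSV missing columns: {missing}")
    return MotionParams(df[MOTION_COLUMNS].to_numpy())


def save_tissues(tissues: TissueMaps, path: str | Path, voxel_size_mm: float = 3.0) -> Path:
    path = Path(path)
    stacked = np.stack([getattr(tissues, c) for c in TISSUE_ORDER], axis=-1)
    nib.save(nib.Nifti1Image(stacked, _affine(voxel_size_mm)), path)
    return path


def load_tissues(path: str | Path) -> TissueMaps:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    return TissueMaps(*(arr[..., i] for i in range(4)))
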