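"""File I/O: NIfTI label/temperature volumes and SurfaceGrid JSON."""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np

from .anatomy import TissueModel
from .geometry import SurfaceGrid

__all__ = [
    "save_labels_nifti",
    "load_labels_nifti",
    "save_volume_nifti",
    "save_grid_json",
    "load_grid_json",
]


def _affine(model: TissueModel) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(model.spacing)
    aff[:3, 3] = model.origin
    return aff


def save_labels_nifti(model: TissueModel, path) -> None:
    img = nib.Nifti1Image(model.labels.astype(np.int16), _affine(model))
    nib.save(img, str(path))


def load_labels_nifti(path, property_table: dict = None) -> TissueModel:
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.diag(aff)[:3].copy()
    if np.any(spacing <= 0):
        raise ValueError("only axis-aligned, positively oriented volumes "
                         "are supported")
    return TissueModel(labels=np.asarray(img.dataobj).astype(np.int16),
                       spacing=spacing, origin=aff[:3, 3].copy(),
                       property_table=property_table)


def save_volume_nifti(volume: np.ndarray, model: TissueModel, path) -> None:
    """Save a float volume (e.g. temperature, SAR) on the model lattice."""
    img = nib.Nifti1Image(volume.astype(np.float32), _affine(model))
    nib.save(img, str(path))


def save_grid_json(grid: SurfaceGrid, path) -> None:
    with open(path, "w") as fh:
        json.dump(grid.to_dict(), fh)


def load_grid_json(path) -> SurfaceGrid:
    with open(path) as fh:
        return SurfaceGrid.from_dict(json.load(fh))
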