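"""NIfTI-1 reading/writing for phantom volumes and masks.

Volumes are stored as float32, masks as uint8 {0, 1}; the affine is
diagonal and encodes the voxel size in mm. The slice axis is the third
array axis throughout the package.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np


def write_volume(path: str | os.PathLike, data: np.ndarray, voxel_size_mm) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size_mm))
    nib.save(img, os.fspath(path))


def write_mask(path: str | os.PathLike, data: np.ndarray, voxel_size_mm) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.uint8), affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size_mm))
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing NIfTI file: {path}")
    img = nib.load(os.fspath(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=np.float64), zooms


def read_mask(path: str | os.PathLike) -> np.ndarray:
    data, _ = read_volume(path)
    return data > 0.5
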