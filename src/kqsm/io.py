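"""NIfTI-1 volume I/O and JSON sidecar handling.

Volumes are read and written as .nii / .nii.gz; the voxel size is taken
from the header zooms (the affine is carried through round trips but
never used for resampling).  Susceptibility values are in ppm, field
maps in the same ppm-scale relative offset.  B0 directions travel
either on the command line or in a JSON sidecar ``{"b0": [x, y, z]}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .kspace_physics import B0Vector, ValidationError, VoxelGrid

__all__ = ["read_volume", "write_volume", "read_b0_sidecar", "write_b0_sidecar"]


def read_volume(path) -> Tuple[np.ndarray, VoxelGrid, np.ndarray]:
    """Load a 3D NIfTI volume -> (values, grid, affine).

    4D inputs are rejected with guidance: multi-echo data should be
    echo-averaged to a single 3D volume upstream.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValidationError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(
            f"{path} is {data.ndim}D; expected a 3D volume "
            "(echo-average multi-echo data before loading)")
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(shape=data.shape, voxel_size=tuple(float(z) for z in zooms))
    return np.asarray(data, dtype=float), grid, np.asarray(img.affine)


def write_volume(values: np.ndarray, grid: VoxelGrid, path,
                 affine: Optional[np.ndarray] = None) -> None:
    """Write a 3D volume as NIfTI-1, preserving the voxel size."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != grid.shape:
        raise ValidationError("volume shape does not match grid")
    if affine is None:
        affine = np.diag(list(grid.voxel_size) + [1.0])
    img = nib.Nifti1Image(values, affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def read_b0_sidecar(path) -> B0Vector:
    """Read ``{"b0": [x, y, z]}`` from a JSON sidecar."""
    with open(path) as fh:
        data = json.load(fh)
    if "b0" not in data:
        raise ValidationError(f"{path} has no 'b0' entry")
    v = np.asarray(data["b0"], dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("b0 sidecar vector has zero norm")
    return B0Vector(tuple(v / n))


def write_b0_sidecar(b0: B0Vector, path) -> None:
    with open(path, "w") as fh:
        json.dump({"b0": list(b0.direction)}, fh)
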