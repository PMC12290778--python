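"""NIfTI-1 volume I/O.

Volumes are written float32 with the voxel size encoded in the affine
(diagonal, RAS); masks and labels round-trip through uint8.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume", "load_volume_with_voxel_size"]


def save_volume(
    path: str | Path,
    data: np.ndarray,
    voxel_size: float,
    dtype=np.float32,
) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), affine)
    img.header.set_zooms((voxel_size,) * 3 + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def load_volume_with_voxel_size(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-4:
        raise ValueError(f"anisotropic voxels not supported: {zooms}")
    return np.asarray(img.dataobj), float(zooms[0])
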