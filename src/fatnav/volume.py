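"""3D image container for navigator and phantom volumes.

A :class:`Volume3D` is a plain scalar grid with per-axis voxel spacing in
millimetres.  Array axes are interpreted as (x, y, z); world coordinates are
measured in mm relative to the volume's geometric centre, which is also the
rotation centre used throughout the package.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume3D"]


class Volume3D:
    """A 3D scalar image with voxel spacing.

    Parameters
    ----------
    data : ndarray
        3D array of finite intensities, axes (x, y, z).
    spacing : tuple of float
        Per-axis voxel size in mm; all entries must be positive.
    """

    def __init__(self, data: np.ndarray, spacing=(1.0, 1.0, 1.0)):
        data = np.asarray(data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume intensities must be finite")
        spacing = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))
        if any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be positive, got {spacing}")
        self.data = data
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def center_index(self) -> np.ndarray:
        """Geometric centre in index coordinates, (shape - 1) / 2."""
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    def index_to_mm(self, idx) -> np.ndarray:
        """Map index coordinates to mm relative to the volume centre."""
        idx = np.asarray(idx, dtype=float)
        return (idx - self.center_index) * np.asarray(self.spacing)

    def mm_to_index(self, pos_mm) -> np.ndarray:
        pos_mm = np.asarray(pos_mm, dtype=float)
        return pos_mm / np.asarray(self.spacing) + self.center_index

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data, self.spacing)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        return nib.Nifti1Image(self.data.astype(np.float32), affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume3D":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), spacing)
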