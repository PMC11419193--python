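"""Centerline volume I/O.

The imaging front-end of the pipeline delivers a skeletonized vessel tree as
a 3D NIfTI volume: nonzero voxels lie on vessel centerlines and carry the
local vessel radius in mm (from a signed-distance transform of the
segmentation); zero is background. The affine maps voxel indices to physical
mm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from emboflow.errors import EmptyCenterlineError, FormatError


@dataclass
class CenterlineVolume:
    """A 3D centerline image: values (radius mm, 0 = background) + affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise FormatError(f"centerline volume must be 3D, got {self.values.ndim}D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-300:
            raise FormatError("affine is singular")
        if (self.values < 0).any():
            raise FormatError("centerline values must be non-negative")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_centerline(self) -> int:
        return int(np.count_nonzero(self.values))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) physical mm coordinates."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))


def read_centerline(path: str | Path) -> CenterlineVolume:
    """Load a centerline NIfTI volume.

    Raises
    ------
    FormatError
        If the file is not a 3D volume.
    EmptyCenterlineError
        If every voxel is zero (no centerline present).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3D volume, got {data.ndim}D")
    vol = CenterlineVolume(values=np.asarray(data, dtype=float), affine=np.asarray(img.affine))
    if vol.n_centerline == 0:
        raise EmptyCenterlineError(f"{path.name}: volume contains no centerline voxels")
    return vol
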