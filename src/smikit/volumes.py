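"""4D image volumes: thin NIfTI wrappers around nibabel."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeStack", "read_nifti", "write_nifti"]


@dataclass
class VolumeStack:
    """A 4D scalar volume (x, y, z, volume) with a spatial affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def flat_signals(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_voxels, n_volumes) view of the masked voxels."""
        if mask is None:
            return self.data.reshape(-1, self.n_volumes)
        return self.data[mask]


def read_nifti(path: str | Path) -> VolumeStack:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    return VolumeStack(data, img.affine)


def write_nifti(stack: VolumeStack | np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> None:
    if isinstance(stack, VolumeStack):
        data, aff = stack.data, stack.affine
    else:
        data, aff = np.asarray(stack), np.eye(4) if affine is None else affine
    nib.Nifti1Image(np.asarray(data, dtype=np.float64), aff).to_filename(str(path))
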