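"""4D volume container and NIfTI-1 round-trip.

World coordinates are millimetres (MNI convention for real data) obtained
through the NIfTI affine; voxel indices are 0-based and never exposed in
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume4D", "read_volume", "write_volume", "mni_like_affine"]


@dataclass
class Volume4D:
    """A 4D fMRI run: (X, Y, Z, T) data, voxel->world affine, repetition time.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Voxel time series.
    affine : ndarray, shape (4, 4)
        Invertible voxel-index -> world-mm transform.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data (X,Y,Z,T), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes (T >= 2)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz, 1/(2*TR)."""
        return 1.0 / (2.0 * self.tr)

    def with_data(self, data: np.ndarray) -> "Volume4D":
        """New volume sharing this affine/TR with replaced data."""
        return Volume4D(data=data, affine=self.affine.copy(), tr=self.tr)

    def voxel_centers_mm(self) -> np.ndarray:
        """World-mm coordinates of every voxel center, shape (X, Y, Z, 3)."""
        return grid_centers_mm(self.data.shape[:3], self.affine)


def grid_centers_mm(grid_shape, affine) -> np.ndarray:
    """World-mm coordinates of voxel centers for a 3D grid, shape (*grid, 3)."""
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    ijk1 = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return (ijk1 @ np.asarray(affine, dtype=float).T)[..., :3]


def mni_like_affine(grid_shape, voxel_size: float = 2.0) -> np.ndarray:
    """Isotropic affine placing the grid center at world (0, 0, 0)."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -voxel_size * (np.asarray(grid_shape, dtype=float) - 1) / 2.0
    return affine


def write_volume(vol: Volume4D, path) -> None:
    """Write a Volume4D to NIfTI-1; TR is stored in the 4th pixdim."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    zooms = list(img.header.get_zooms()[:3]) + [vol.tr]
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_volume(path, tr: float | None = None) -> Volume4D:
    """Read a 4D NIfTI-1 file.

    Parameters
    ----------
    tr : float, optional
        Override for the repetition time when the header carries none
        (header pixdim[4] <= 0).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValueError(
                f"{path}: no repetition time in the header; pass tr= explicitly"
            )
    return Volume4D(data=np.asarray(data, dtype=float), affine=np.asarray(img.affine), tr=float(tr))
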