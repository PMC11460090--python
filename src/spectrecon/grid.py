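"""Voxel lattices and the image containers used throughout the package.

All images live on an isotropic cubic lattice (default 4.8 mm, the SPECT
matrix after resampling a 256x256 acquisition to 128x128).  World
coordinates are symmetric about the volume centre: axis coordinates are
``(index - (n-1)/2) * voxel_size``, so for odd extents the centre voxel
sits exactly at the origin and for even extents the origin falls between
the two central voxels.  Axis order is (z, y, x) for 3D volumes and
(y, x) for single-slice 2D work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = ["VoxelGrid", "ActivityImage", "MuMap"]


@dataclass(frozen=True)
class VoxelGrid:
    """An isotropic voxel lattice with a centred world frame.

    Parameters
    ----------
    dims : tuple of int
        Grid extents, ``(ny, nx)`` or ``(nz, ny, nx)``.
    voxel_size_mm : float
        Isotropic voxel edge length in mm.
    """

    dims: Tuple[int, ...]
    voxel_size_mm: float = 4.8

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if len(self.dims) not in (2, 3) or any(int(d) < 1 for d in self.dims):
            raise ValueError("dims must be 2 or 3 positive integers")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (= cm^3); in 2D the slice thickness
        is taken equal to the voxel size."""
        return (self.voxel_size_mm / 10.0) ** 3

    @property
    def voxel_area_mm2(self) -> float:
        return self.voxel_size_mm ** 2

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.dims[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size_mm

    def coord_grids(self) -> Tuple[np.ndarray, ...]:
        """Dense mesh of voxel-centre world coordinates, one array per axis."""
        axes = [self.axis_coords(a) for a in range(self.ndim)]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def central_slice(self) -> "VoxelGrid":
        """The 2D grid of the central transaxial plane of a 3D grid."""
        if self.ndim == 2:
            return self
        return VoxelGrid(self.dims[1:], self.voxel_size_mm)


@dataclass
class _GriddedImage:
    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if np.any(self.values < 0):
            raise ValueError("image values must be nonnegative")

    def copy_with(self, values: np.ndarray):
        return replace(self, values=np.asarray(values, dtype=float))

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class ActivityImage(_GriddedImage):
    """Activity-concentration image in kBq/ml on a :class:`VoxelGrid`.

    ``role`` tags what the image represents: the ground-truth digital
    reference object (``"ground-truth"``), a PET prior (``"pet-prior"``)
    or a reconstruction (``"reconstruction"``).
    """

    role: str = "ground-truth"
    meta: dict = field(default_factory=dict)

    @property
    def total_activity_mbq(self) -> float:
        """Total activity in MBq: sum(kBq/ml) x voxel volume (ml) / 1000."""
        return self.total * self.grid.voxel_volume_ml / 1000.0


@dataclass
class MuMap(_GriddedImage):
    """Linear attenuation coefficients (1/cm) at the imaging photopeak."""
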