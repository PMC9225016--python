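"""Voxel volume container on a scanner-centred grid."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np


@dataclass
class VoxelVolume:
    """3-D image grid (activity, attenuation, or reconstruction).

    ``values[i, j, k]`` indexes (x, y, z).  ``origin`` is the physical
    coordinate (mm) of the *centre* of voxel (0, 0, 0) in scanner-centred
    coordinates; ``voxel_size`` is the (dx, dy, dz) spacing in mm.
    """

    values: np.ndarray
    voxel_size: Tuple[float, float, float]
    origin: Tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @classmethod
    def centred(cls, dims, voxel_size, fill: float = 0.0, centre=(0.0, 0.0, 0.0)):
        """Grid of ``dims`` voxels whose physical centre is ``centre``."""
        dims = tuple(int(d) for d in dims)
        vs = (voxel_size,) * 3 if np.isscalar(voxel_size) else tuple(voxel_size)
        origin = tuple(c - (d - 1) / 2.0 * s for c, d, s in zip(centre, dims, vs))
        return cls(values=np.full(dims, fill, dtype=np.float64), voxel_size=vs, origin=origin)

    @property
    def dims(self):
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.voxel_size[axis]

    def grid_min(self) -> np.ndarray:
        """Lower physical corner of the grid (voxel faces, not centres)."""
        return np.array(self.origin) - np.array(self.voxel_size) / 2.0

    def grid_max(self) -> np.ndarray:
        return self.grid_min() + np.array(self.dims) * np.array(self.voxel_size)

    def meshgrid(self):
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def like(self, values: np.ndarray | None = None, fill: float = 0.0) -> "VoxelVolume":
        vals = np.full(self.dims, fill) if values is None else np.asarray(values, dtype=float)
        return VoxelVolume(values=vals, voxel_size=self.voxel_size, origin=self.origin)

    def total(self) -> float:
        return float(self.values.sum())
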