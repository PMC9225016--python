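"""Siddon ray-tracing forward and back projection.

One ray per bin is traced between the crystal front-face centres supplied by
a :class:`~polypet.geometry.CrystalMap` (the convention of the reconstruction
library this toolkit models).  Optionally each bin can average a small bundle
of sub-rays whose endpoints are shifted across the crystal faces
(``n_rays_tang`` x ``n_rays_axial`` stratified offsets over one pitch),
modelling the finite detector aperture.  The forward and back projectors
share one traversal kernel and are exact adjoints of each other.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .geometry import CrystalMap
from .projdata import ProjData, bin_detector_lut
from .volume import VoxelVolume

N_RAYS_TANG = 1
N_RAYS_AXIAL = 1

_lut_cache: dict = {}


def _offsets(n: int, pitch: float) -> np.ndarray:
    """Stratified sub-ray offsets spanning one crystal pitch."""
    if n < 1:
        raise ValueError("ray count must be >= 1")
    return ((np.arange(n) + 0.5) / n - 0.5) * pitch


def _face_tangents(cmap: CrystalMap) -> np.ndarray:
    """Transaxial unit tangent of each detector's face, one ring's worth."""
    n = cmap.spec.n_detectors_per_ring
    normals = cmap.inward_normals[:n]
    tang = np.column_stack([normals[:, 1], -normals[:, 0]])
    return np.ascontiguousarray(tang)


def _luts(spec, tangential_size):
    key = (spec, tangential_size)
    if key not in _lut_cache:
        dA, dB, valid = bin_detector_lut(spec, tangential_size)
        _lut_cache[key] = (dA, dB, np.ascontiguousarray(valid, dtype=np.uint8))
    return _lut_cache[key]


def _grid_args(vol: VoxelVolume):
    gmin = vol.grid_min()
    return (gmin[0], gmin[1], gmin[2],
            vol.voxel_size[0], vol.voxel_size[1], vol.voxel_size[2])


def siddon_trace(p1, p2, vol: VoxelVolume):
    """Voxels crossed by the segment p1 -> p2 with intersection lengths (mm).

    Returns a list of ``((i, j, k), length)`` ordered along the ray; empty if
    the ray misses the volume.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.allclose(p1, p2):
        raise ValueError("degenerate ray: coincident endpoints")
    dims = vol.dims
    cap = dims[0] + dims[1] + dims[2] + 3
    idx = np.zeros((cap, 3), dtype=np.int64)
    lens = np.zeros(cap)
    gmin = vol.grid_min()
    n = _kernels.trace_ray(gmin[0], gmin[1], gmin[2],
                           vol.voxel_size[0], vol.voxel_size[1], vol.voxel_size[2],
                           dims[0], dims[1], dims[2],
                           p1[0], p1[1], p1[2], p2[0], p2[1], p2[2],
                           idx, lens)
    return [(tuple(int(v) for v in idx[m]), float(lens[m])) for m in range(n)]


def forward_project(vol: VoxelVolume, cmap: CrystalMap, template: ProjData,
                    mask: np.ndarray | None = None,
                    n_rays_tang: int = N_RAYS_TANG,
                    n_rays_axial: int = N_RAYS_AXIAL) -> ProjData:
    """Line-integral projection of ``vol`` into the template's bin structure.

    Each bin receives the (sub-ray averaged) sum over voxels of value x
    intersection length along the LOR between the crystal faces of its
    detector pair.  ``mask`` (same shape as the sinogram) restricts
    computation to selected bins.
    """
    spec = template.spec
    dA, dB, valid = _luts(spec, template.tangential_size)
    out = np.zeros_like(template.values)
    if mask is None:
        m = np.ones(out.shape, dtype=np.uint8)
    else:
        m = np.ascontiguousarray(mask != 0, dtype=np.uint8)
    gargs = _grid_args(vol)
    tang = _face_tangents(cmap)
    offs_t = _offsets(n_rays_tang, spec.crystal_pitch_trans)
    if template.rebinned:
        posxy = np.ascontiguousarray(cmap.positions_by_ring()[0, :, :2])
        _kernels.fwd_project_2d(vol.values, *gargs, posxy, tang,
                                template.slice_z(), dA, dB, valid, m,
                                offs_t, out)
    else:
        pos = np.ascontiguousarray(cmap.positions_by_ring())
        offs_z = _offsets(n_rays_axial, spec.crystal_pitch_axial)
        _kernels.fwd_project_3d(vol.values, *gargs, pos, tang, dA, dB, valid, m,
                                template.max_ring_diff, offs_t, offs_z, out)
    return template.copy_with(out, geometry_class=cmap.geometry_class)


def back_project(data: ProjData, cmap: CrystalMap,
                 vol_template: VoxelVolume,
                 n_rays_tang: int = N_RAYS_TANG,
                 n_rays_axial: int = N_RAYS_AXIAL) -> VoxelVolume:
    """Exact adjoint of :func:`forward_project` (same sub-ray bundle)."""
    spec = data.spec
    dA, dB, valid = _luts(spec, data.tangential_size)
    out = np.zeros(vol_template.dims)
    gargs = _grid_args(vol_template)
    vals = np.ascontiguousarray(data.values)
    tang = _face_tangents(cmap)
    offs_t = _offsets(n_rays_tang, spec.crystal_pitch_trans)
    if data.rebinned:
        posxy = np.ascontiguousarray(cmap.positions_by_ring()[0, :, :2])
        _kernels.back_project_2d(vals, *gargs, posxy, tang, data.slice_z(),
                                 dA, dB, valid, offs_t, out)
    else:
        pos = np.ascontiguousarray(cmap.positions_by_ring())
        offs_z = _offsets(n_rays_axial, spec.crystal_pitch_axial)
        _kernels.back_project_3d(vals, *gargs, pos, tang, dA, dB, valid,
                                 data.max_ring_diff, offs_t, offs_z, out)
    return vol_template.like(out)
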