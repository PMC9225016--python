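"""Single scatter simulation (SSS), tail fitting, and scatter estimation.

The SSS estimate integrates, over a coarse lattice of scatter points inside
the attenuating object, the probability that one photon of a pair Compton
scatters exactly once and both photons still land in the energy window.
Detector positions are taken from the crystal map, so the estimate follows
whichever geometry interpretation (flat block faces or cylinder) is used for
reconstruction -- the scatter sinogram *shape* depends on it.

Two pipeline modes exist: ``full_resolution_2d`` computes direct (equal-ring)
planes at the scanner's native sampling (the default for block geometries),
and ``downsampled_upsampled`` runs SSS on a half-detector/half-ring version
of the scanner and interpolates back up.  The up-sampler is kept in its
historically defective form for block-tagged input (see
:func:`upsample_scatter`) and is exercised by a width diagnostic rather than
by the default pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from . import _kernels
from .corrections import CorrectionSet
from .geometry import BLOCKS, CYLINDRICAL, CrystalMap, ScannerSpec, build_crystal_map
from .mc import MU_WATER_511, _E_TAB, MU_RATIO_TAB
from .projdata import ProjData
from .projector import _luts
from .volume import VoxelVolume

FULL_RESOLUTION_2D = "full_resolution_2d"
DOWNSAMPLED_UPSAMPLED = "downsampled_upsampled"


@dataclass
class ScatterConfig:
    scatter_point_spacing: float = 20.0      # mm lattice pitch
    downsample_detectors: int = 2
    downsample_rings: int = 2
    mode: str = FULL_RESOLUTION_2D
    energy_window: Tuple[float, float] = (425.0, 650.0)
    n_estimation_iterations: int = 3
    # tail bins: ACF below this (at most ~19 mm of water) -- close enough to
    # the object edge for statistics, far enough that no unscattered
    # coincidences leak into the fit region
    tail_threshold: float = 1.2
    tail_fit_per_slice: bool = True          # one scale per axial slice
    mu_support_fraction: float = 0.25        # of water mu, for point placement

    def __post_init__(self):
        if self.scatter_point_spacing <= 0:
            raise ValueError("scatter point spacing must be positive")
        if self.downsample_detectors < 1 or self.downsample_rings < 1:
            raise ValueError("downsampling factors must be >= 1")
        if self.mode not in (FULL_RESOLUTION_2D, DOWNSAMPLED_UPSAMPLED):
            raise ValueError(f"unknown SSS mode {self.mode!r}")


def _scatter_points(mu_map: VoxelVolume, cfg: ScatterConfig):
    """Regular lattice of scatter points restricted to the attenuating medium."""
    h = cfg.scatter_point_spacing
    gmin = mu_map.grid_min()
    gmax = mu_map.grid_max()
    axes = [np.arange(gmin[a] + h / 2, gmax[a], h) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.floor((pts - gmin) / np.array(mu_map.voxel_size)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(mu_map.dims)), axis=1)
    pts, idx = pts[ok], idx[ok]
    mu_pt = mu_map.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    keep = mu_pt > cfg.mu_support_fraction * MU_WATER_511
    return np.ascontiguousarray(pts[keep]), np.ascontiguousarray(mu_pt[keep])


def sss(activity: VoxelVolume, mu_map: VoxelVolume, cmap: CrystalMap,
        cfg: ScatterConfig | None = None,
        tangential_size: int | None = None) -> ProjData:
    """Single-scatter sinogram on direct planes (rebinned layout).

    Returns a rebinned (slice, view, tangential) sinogram: equal-ring planes
    are computed from the model and in-between slices are filled by averaging
    their neighbours.  Linear in the activity image.  An empty attenuation
    support yields an all-zero sinogram.
    """
    cfg = cfg or ScatterConfig()
    spec = cmap.spec
    out = ProjData.zeros(spec, tangential_size, geometry_class=cmap.geometry_class,
                         rebinned=True)
    pts, mu_pt = _scatter_points(mu_map, cfg)
    if len(pts) == 0 or activity.values.sum() == 0:
        return out
    dA, dB, valid = _luts(spec, out.tangential_size)
    det_pos = np.ascontiguousarray(cmap.centres)
    det_norm = np.ascontiguousarray(cmap.inward_normals)
    D, S = det_pos.shape[0], pts.shape[0]
    em = np.zeros((D, S))
    tau = np.zeros((D, S))
    agmin = activity.grid_min()
    mgmin = mu_map.grid_min()
    _kernels.sss_leg_integrals(det_pos, pts,
                               activity.values, agmin[0], agmin[1], agmin[2],
                               *activity.voxel_size,
                               mu_map.values, mgmin[0], mgmin[1], mgmin[2],
                               *mu_map.voxel_size, em, tau)
    R = spec.n_rings
    direct = np.zeros((R, out.n_views, out.tangential_size))
    _kernels.sss_direct_planes(det_pos, det_norm, spec.n_detectors_per_ring,
                               pts, mu_pt, em, tau, dA, dB,
                               np.ascontiguousarray(valid, dtype=np.uint8),
                               _E_TAB, MU_RATIO_TAB,
                               float(cfg.energy_window[0]), float(cfg.energy_window[1]),
                               direct)
    # place direct planes on even slices, interpolate odd slices
    out.values[0::2] = direct
    out.values[1::2] = 0.5 * (direct[:-1] + direct[1:])
    return out


def downsampled_spec(spec: ScannerSpec, cfg: ScatterConfig) -> ScannerSpec:
    """Half-detector / half-ring version of the scanner for coarse SSS.

    Crystal counts per block are divided by the factors and pitches scaled up
    so faces and axial length are preserved; the apothem is pinned to the
    original value.
    """
    fd, fr = cfg.downsample_detectors, cfg.downsample_rings
    if spec.crystals_per_block_trans % fd or spec.crystals_per_block_axial % fr:
        raise ValueError("downsampling factors must divide the crystal counts")
    return dataclasses.replace(
        spec,
        crystals_per_block_trans=spec.crystals_per_block_trans // fd,
        crystals_per_block_axial=spec.crystals_per_block_axial // fr,
        crystal_pitch_trans=spec.crystal_pitch_trans * fd,
        crystal_pitch_axial=spec.crystal_pitch_axial * fr,
        apothem=spec.effective_apothem)


def sss_downsampled(activity: VoxelVolume, mu_map: VoxelVolume, cmap: CrystalMap,
                    cfg: ScatterConfig) -> ProjData:
    """SSS on the coarse scanner (same geometry class, same apothem)."""
    coarse = build_crystal_map(downsampled_spec(cmap.spec, cfg), cmap.geometry_class)
    return sss(activity, mu_map, coarse, cfg)


def upsample_scatter(low_res: ProjData, target_template: ProjData) -> ProjData:
    """Interpolate a coarse SSS sinogram to the scanner's native sampling.

    Views and slices are mapped through their physical coordinates (angle and
    axial position).  The tangential axis depends on the geometry tag:

    * ``Cylindrical`` (or untagged) input is mapped through the cylindrical
      radial coordinate ``s = r sin(pi t / N)`` of each sampling -- the
      correct stretch for a ring scanner.
    * ``BlocksOnCylindrical`` input reproduces the historical defect of the
      cylindrical-only rebinning chain: the coarse tangential grid is treated
      as if it already had the target bin size (centre-aligned, no stretch),
      which yields a visibly too-narrow scatter profile.  The default block
      pipeline therefore avoids up-sampling entirely (full-resolution 2-D
      mode); this path is retained for the width-mismatch diagnostic.

    Identity when the two samplings coincide; a constant sinogram stays
    constant.
    """
    if not low_res.rebinned or not target_template.rebinned:
        raise ValueError("up-sampling operates on rebinned sinograms")
    lspec, tspec = low_res.spec, target_template.spec
    Sl, Vl, Tl = low_res.values.shape
    St, Vt, Tt = target_template.values.shape

    # view axis: both cover [0, pi)
    vi = np.arange(Vt) * (Vl / Vt)
    # axial axis: physical slice positions
    zl = low_res.slice_z()
    zt = target_template.slice_z()
    si = np.interp(zt, zl, np.arange(Sl))
    # tangential axis
    tt = np.arange(Tt) - Tt // 2
    if low_res.geometry_class == BLOCKS:
        ti = tt + Tl // 2                              # defective 1:1 placement
    else:
        r = tspec.effective_apothem
        s_fine = r * np.sin(np.pi * tt / tspec.n_detectors_per_ring)
        tl = np.arange(Tl) - Tl // 2
        s_coarse = lspec.effective_apothem * np.sin(
            np.pi * tl / lspec.n_detectors_per_ring)
        ti = np.interp(s_fine, s_coarse, np.arange(Tl))
    ti = np.clip(ti, 0, Tl - 1)
    si = np.clip(si, 0, Sl - 1)
    vi = np.clip(vi, 0, Vl - 1)
    coords = np.meshgrid(si, vi, ti, indexing="ij")
    vals = ndimage.map_coordinates(low_res.values, coords, order=1, mode="nearest")
    return target_template.copy_with(vals, geometry_class=low_res.geometry_class)


def tail_fit_scale(sss_estimate: ProjData, measured: ProjData, acf: ProjData,
                   cfg: ScatterConfig | None = None,
                   randoms: ProjData | None = None) -> ProjData:
    """Scale the SSS estimate to the measured scatter tails.

    Tail bins lie outside the object (ACF below the configured threshold but
    on accepted LORs); the global scale is the least-squares fit of the
    estimate to measured - randoms over those bins.  Raises if the object
    leaves no tails in the FOV.
    """
    cfg = cfg or ScatterConfig()
    if sss_estimate.values.shape != measured.values.shape:
        raise ValueError("sinogram shapes differ")
    est = sss_estimate.values
    tails = (acf.values > 0) & (acf.values < cfg.tail_threshold) & (est > 0)
    if not np.any(tails):
        raise ValueError("no tail bins: object fills the field of view")
    target = measured.values.astype(float)
    if randoms is not None:
        target = target - randoms.values
    num = float((est[tails] * target[tails]).sum())
    den = float((est[tails] ** 2).sum())
    scale = max(num / den, 0.0) if den > 0 else 0.0
    if cfg.tail_fit_per_slice and est.ndim == 3:
        # one scale per axial slice; slices with weak tails fall back to the
        # global value (a slice needs enough tail signal for a stable fit)
        scales = np.full(est.shape[0], scale)
        for s in range(est.shape[0]):
            m = tails[s]
            den_s = float((est[s][m] ** 2).sum())
            cnt_s = float(target[s][m].sum())
            if den_s > 0 and cnt_s >= 20:
                scales[s] = max(float((est[s][m] * target[s][m]).sum()) / den_s,
                                0.0)
        out = sss_estimate.copy_with(est * scales[:, None, None])
        out.scale = scale
        out.slice_scales = scales
        return out
    out = sss_estimate.copy_with(est * scale)
    out.scale = scale
    return out


def estimate_scatter(measured: ProjData, acf: ProjData, randoms: ProjData | None,
                     mu_map: VoxelVolume, cmap: CrystalMap,
                     vol_template: VoxelVolume,
                     cfg: ScatterConfig | None = None,
                     recon_iters: int = 8) -> ProjData:
    """Iterated scatter estimation: reconstruct, simulate, tail-fit, average.

    Each pass reconstructs the (attenuation- and randoms-corrected, current
    scatter subtracted) data with a short MLEM run, feeds the activity
    estimate to SSS and tail-fits the result; the scaled estimates of all
    passes are averaged.  Output is non-negative everywhere.
    """
    from .recon import mlem_reconstruct   # local import to avoid a cycle

    cfg = cfg or ScatterConfig()
    estimates = []
    current = None
    for _ in range(max(1, cfg.n_estimation_iterations)):
        corr = CorrectionSet(acf=acf, randoms=randoms, scatter=current)
        act = mlem_reconstruct(measured, corr, cmap, vol_template,
                               n_iter=recon_iters)
        est = sss(act, mu_map, cmap, cfg, tangential_size=measured.tangential_size)
        est = tail_fit_scale(est, measured, acf, cfg, randoms=randoms)
        estimates.append(est.values)
        current = measured.copy_with(est.values)
    out = measured.copy_with(np.maximum(np.mean(estimates, axis=0), 0.0))
    return out
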