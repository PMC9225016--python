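"""Image-quality metrics: FWHM, uniformity (COV), and rod contrast.

The FWHM follows the standard resolution procedure for point-source
profiles: the peak value is refined by a parabolic fit through the three
samples around the maximum, and the half-maximum crossings on either side
are located by linear interpolation between the neighbouring samples.
Contrast and background variability follow the customary hot/cold-rod
definitions with background ROIs of the same diameter as the rod.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume import VoxelVolume


def _parabolic_peak(profile: np.ndarray, i: int):
    """Refined (position, value) of the peak around sample ``i``."""
    if i == 0 or i == len(profile) - 1:
        return float(i), float(profile[i])
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # degenerate / flat
        return float(i), float(profile[i])
    d = 0.5 * (y0 - y2) / denom
    return i + d, y1 - 0.25 * (y0 - y2) * d


def fwhm_1d(profile, spacing_mm: float = 1.0, parabolic_peak: bool = True) -> float:
    """Full width at half maximum of a sampled 1-D profile (mm).

    Requires a positive, unimodal-enough peak with the half level crossed on
    both sides.  With ``parabolic_peak=False`` the raw maximum sample is used
    as the peak value instead of the parabolic refinement.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    i = int(np.argmax(p))
    if p[i] <= 0:
        raise ValueError("profile must have a positive peak")
    if parabolic_peak:
        _, peak = _parabolic_peak(p, i)
    else:
        peak = p[i]
    half = peak / 2.0
    # walk left
    li = i
    while li > 0 and p[li] > half:
        li -= 1
    if p[li] > half:
        raise ValueError("half maximum not crossed on the left")
    left = li + (half - p[li]) / (p[li + 1] - p[li])
    # walk right
    ri = i
    n = len(p)
    while ri < n - 1 and p[ri] > half:
        ri += 1
    if p[ri] > half:
        raise ValueError("half maximum not crossed on the right")
    right = ri - (half - p[ri]) / (p[ri - 1] - p[ri])
    return float((right - left) * spacing_mm)


def _band_profile(vals, axis, peak, half_voxels):
    """Response function along ``axis``: the volume summed over bands of
    ``half_voxels`` around the peak in the two orthogonal directions."""
    sl = [None, None, None]
    for a in range(3):
        if a == axis:
            sl[a] = slice(None)
        else:
            lo = max(peak[a] - half_voxels[a], 0)
            hi = min(peak[a] + half_voxels[a] + 1, vals.shape[a])
            sl[a] = slice(lo, hi)
    sub = vals[tuple(sl)]
    axes = tuple(a for a in range(3) if a != axis)
    return sub.sum(axis=axes)


def fwhm_3d(volume: VoxelVolume, around=None, parabolic_peak: bool = True,
            band_sum: bool = True):
    """FWHM along x, y, z of the point-response around the image maximum.

    Follows the standard image-quality resolution procedure: each direction's
    response function is formed by summing the volume over bands of about
    twice the (initially estimated) FWHM in the two orthogonal directions,
    then measuring :func:`fwhm_1d` on that profile.  ``band_sum=False``
    measures raw single-row profiles through the peak voxel instead.
    ``around`` restricts the peak search to the vicinity (11 voxels) of that
    physical point.
    """
    vals = volume.values
    if around is not None:
        centre = np.round((np.asarray(around) - np.asarray(volume.origin))
                          / np.asarray(volume.voxel_size)).astype(int)
        lo = np.maximum(centre - 11, 0)
        hi = np.minimum(centre + 12, np.array(volume.dims))
        sub = vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        rel = np.unravel_index(int(np.argmax(sub)), sub.shape)
        peak = tuple(int(v) for v in lo + np.array(rel))
    else:
        peak = tuple(int(v) for v in
                     np.unravel_index(int(np.argmax(vals)), vals.shape))
    i, j, k = peak
    first = (fwhm_1d(vals[:, j, k], volume.voxel_size[0], parabolic_peak),
             fwhm_1d(vals[i, :, k], volume.voxel_size[1], parabolic_peak),
             fwhm_1d(vals[i, j, :], volume.voxel_size[2], parabolic_peak))
    if not band_sum:
        return first
    # band half-widths ~ 2 x first-pass FWHM (at least 2 voxels)
    half = [max(2, int(math.ceil(2.0 * first[a] / volume.voxel_size[a])))
            for a in range(3)]
    out = []
    for a in range(3):
        prof = _band_profile(vals, a, peak, half)
        out.append(fwhm_1d(prof, volume.voxel_size[a], parabolic_peak))
    return tuple(out)


def cov_roi(volume: VoxelVolume, radius_mm: float = 100.0,
            length_mm: float = 50.0, centre=(0.0, 0.0, 0.0)):
    """Mean, SD and coefficient of variation in a centred cylindrical ROI.

    The default ROI (radius 100 mm, length 50 mm) is the uniformity region
    used for uniform-cylinder quality checks.
    """
    x, y, z = volume.meshgrid()
    roi = (((x - centre[0]) ** 2 + (y - centre[1]) ** 2) <= radius_mm ** 2) \
        & (np.abs(z - centre[2]) <= length_mm / 2.0)
    vals = volume.values[np.broadcast_to(roi, volume.dims)]
    if vals.size == 0:
        raise ValueError("ROI contains no voxels")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    cov = sd / mean if mean != 0 else math.inf
    return mean, sd, cov


def radial_profile(volume: VoxelVolume, r_max_mm: float, n_bins: int = 40,
                   z_halfwidth_mm: float | None = None):
    """Mean voxel value per annulus of equal radial width around the axis.

    Returns ``(bin_centres_mm, means)``.  A ring-artefact-free uniform
    cylinder gives a flat profile; the ratio max/min of the annulus means is
    a simple non-uniformity score.
    """
    x, y, z = volume.meshgrid()
    r = np.sqrt(x * x + y * y)
    sel = np.broadcast_to(r < r_max_mm, volume.dims)
    if z_halfwidth_mm is not None:
        sel = sel & np.broadcast_to(np.abs(z) <= z_halfwidth_mm, volume.dims)
    rr = np.broadcast_to(r, volume.dims)[sel]
    vv = volume.values[sel]
    edges = np.linspace(0, r_max_mm, n_bins + 1)
    idx = np.clip(np.digitize(rr, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=vv, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    centres = (edges[:-1] + edges[1:]) / 2
    return centres, means


def nonuniformity(volume: VoxelVolume, r_max_mm: float = 80.0,
                  n_bins: int = 40, z_halfwidth_mm: float | None = None) -> float:
    """max/min ratio of the annulus means inside ``r_max_mm``."""
    _, means = radial_profile(volume, r_max_mm, n_bins, z_halfwidth_mm)
    means = means[np.isfinite(means)]
    if means.size == 0 or means.min() <= 0:
        return math.inf
    return float(means.max() / means.min())


@dataclass
class RodReport:
    diameter: float
    kind: str
    contrast_percent: float
    background_variability_percent: float


def _disc_mean(volume, cx, cy, diameter, zsel):
    x, y, z = volume.meshgrid()
    m = ((x - cx) ** 2 + (y - cy) ** 2) <= (diameter / 2.0) ** 2
    m = np.broadcast_to(m, volume.dims) & zsel
    vals = volume.values[m]
    return float(vals.mean()) if vals.size else math.nan


def nema_contrast(volume: VoxelVolume, rods, hot_ratio: float = 4.0,
                  bg_radius_mm: float = 30.0, n_bg_rois: int = 12,
                  axial_halfwidth_mm: float = 10.0):
    """Percent contrast and background variability per rod.

    Hot rods: ``100 (H/B - 1)/(ratio - 1)``; cold/air rods: ``100 (1 - C/B)``;
    background variability: ``100 SD(bg ROI means)/B`` over a ring of
    circular background ROIs of the rod's diameter placed at radius
    ``bg_radius_mm`` around the phantom centre.  Means are taken over a slab
    of ``2 x axial_halfwidth_mm`` around the axial centre.
    """
    x, y, z = volume.meshgrid()
    zsel = np.broadcast_to(np.abs(z) <= axial_halfwidth_mm, volume.dims)
    reports = []
    for rod in rods:
        diam, kind = rod["diameter"], rod["kind"]
        rod_mean = _disc_mean(volume, rod["cx"], rod["cy"], diam, zsel)
        bg_means = []
        for i in range(n_bg_rois):
            ang = 2 * math.pi * i / n_bg_rois + math.pi / n_bg_rois
            bx = bg_radius_mm * math.cos(ang)
            by = bg_radius_mm * math.sin(ang)
            bg_means.append(_disc_mean(volume, bx, by, diam, zsel))
        bg_means = np.array(bg_means)
        B = float(np.nanmean(bg_means))
        if kind == "hot":
            contrast = 100.0 * (rod_mean / B - 1.0) / (hot_ratio - 1.0)
        else:
            contrast = 100.0 * (1.0 - rod_mean / B)
        bv = 100.0 * float(np.nanstd(bg_means, ddof=0)) / B
        reports.append(RodReport(diam, kind, contrast, bv))
    return reports
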