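"""MLEM reconstruction with multiplicative and additive correction factors.

Ordinary-Poisson MLEM: the measured data stay in raw count units and the
system model is ``ybar = c * (A lambda) + b`` with per-bin multiplicative
factor ``c = eps_i eps_j g / ACF`` and additive background
``b = randoms + scatter``.  The update

    lambda <- lambda / sens * A^T [ c * m / ybar ],    sens = A^T c

preserves non-negativity and never decreases the Poisson log-likelihood.
"""

from __future__ import annotations

import math

import numpy as np

from .corrections import CorrectionSet
from .geometry import CrystalMap
from .projdata import ProjData
from .projector import back_project, forward_project, _luts
from .volume import VoxelVolume


def _valid_mask(template: ProjData) -> np.ndarray:
    _, _, valid = _luts(template.spec, template.tangential_size)
    valid = valid.astype(bool)
    if template.rebinned:
        m = np.broadcast_to(valid[None], template.values.shape).copy()
    else:
        R = template.spec.n_rings
        r = np.arange(R)
        ring_ok = np.abs(r[:, None] - r[None, :]) <= template.max_ring_diff
        m = ring_ok[:, :, None, None] & valid[None, None]
        m = np.broadcast_to(m, template.values.shape).copy()
    return m


def fov_radius(template: ProjData) -> float:
    """Largest |s| covered by the tangential window."""
    spec = template.spec
    N = spec.n_detectors_per_ring
    t_max = template.tangential_size // 2 - 1
    return spec.effective_apothem * math.sin(math.pi * t_max / N)


def sensitivity_image(cmap: CrystalMap, vol_template: VoxelVolume,
                      template: ProjData,
                      corrections: CorrectionSet | None = None,
                      **ray_kw) -> VoxelVolume:
    """Back-projection of the per-bin multiplicative model coefficient.

    With unit normalisation and unit ACF this is the plain back-projection of
    ones over all accepted bins; it is strictly positive inside the FOV.
    """
    corrections = corrections or CorrectionSet()
    c = corrections.multiplicative(template) * _valid_mask(template)
    sino = template.copy_with(c)
    return back_project(sino, cmap, vol_template, **ray_kw)


def mlem_reconstruct(data: ProjData, corrections: CorrectionSet | None,
                     cmap: CrystalMap, vol_template: VoxelVolume,
                     n_iter: int = 40, track_likelihood: bool = False,
                     fov_mask_radius: float | None = None,
                     initial: VoxelVolume | None = None,
                     **ray_kw) -> VoxelVolume:
    """Run ``n_iter`` MLEM iterations; returns the reconstruction.

    The initial image is uniform ones inside the FOV cylinder mask (or
    ``initial`` if given).  Voxels with zero sensitivity are masked out.
    With ``track_likelihood`` the Poisson log-likelihood (up to the
    m-dependent constant) is recorded per iteration on the result as
    ``loglik``.
    """
    corrections = corrections or CorrectionSet()
    valid = _valid_mask(data)
    c = corrections.multiplicative(data) * valid
    b = corrections.additive(data) * valid
    m = data.values * valid
    if np.any(m < 0):
        raise ValueError("measured data must be non-negative")

    sens = sensitivity_image(cmap, vol_template, data, corrections, **ray_kw).values
    if fov_mask_radius is None:
        fov_mask_radius = fov_radius(data)
    x, y, _ = vol_template.meshgrid()
    fov = (x * x + y * y) <= fov_mask_radius ** 2
    support = (sens > 0) & np.broadcast_to(fov, vol_template.dims)

    if initial is not None:
        lam = np.where(support, initial.values, 0.0)
    else:
        lam = np.where(support, 1.0, 0.0)
    sino_tmpl = data.copy_with(np.zeros_like(data.values))
    # exclude counts on LORs that barely graze the reconstruction volume:
    # their model value can never rise above ~0 and the update would amplify
    # them without bound
    support_proj = forward_project(vol_template.like(support.astype(float)),
                                   cmap, sino_tmpl,
                                   mask=(m > 0).astype(np.uint8),
                                   **ray_kw).values
    mask_m = ((m > 0) & (support_proj > 1e-3)).astype(np.uint8)
    logliks = []
    sum_b = float(b.sum())
    for _ in range(n_iter):
        proj = forward_project(vol_template.like(lam), cmap, sino_tmpl,
                               mask=mask_m, **ray_kw).values
        ybar = c * proj + b
        nz = mask_m.astype(bool)
        if track_likelihood:
            # likelihood of the current iterate (consistent lam everywhere)
            ll = float(np.sum(m[nz] * np.log(np.maximum(ybar[nz], 1e-300))))
            ll -= float((lam * sens).sum()) + sum_b
            logliks.append(ll)
        q = np.zeros_like(ybar)
        q[nz] = c[nz] * m[nz] / np.maximum(ybar[nz], 1e-30)
        upd = back_project(data.copy_with(q), cmap, vol_template, **ray_kw).values
        lam = np.where(support, lam * upd / np.maximum(sens, 1e-30), 0.0)
    out = vol_template.like(lam)
    if track_likelihood:
        out.loglik = logliks
    return out


def poisson_loglik(data: ProjData, corrections: CorrectionSet | None,
                   cmap: CrystalMap, lam: VoxelVolume) -> float:
    """Poisson log-likelihood of the data under image ``lam`` (no m! term)."""
    corrections = corrections or CorrectionSet()
    valid = _valid_mask(data)
    c = corrections.multiplicative(data) * valid
    b = corrections.additive(data) * valid
    m = data.values * valid
    proj = forward_project(lam, cmap, data.copy_with(np.zeros_like(m)),
                           mask=valid.astype(np.uint8)).values
    ybar = c * proj + b
    nz = m > 0
    ll = float(np.sum(m[nz] * np.log(np.maximum(ybar[nz], 1e-300))))
    return ll - float(ybar.sum())
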