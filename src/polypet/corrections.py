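"""Normalisation, attenuation and randoms factors for the MLEM pipeline.

Conventions: ``NormFactors`` stores *efficiencies* (crystal factors eps_i and
geometry-symmetric factors g, both near 1 for a well-behaved scanner); the
combined per-bin efficiency is ``eps_i * eps_j * g``.  The attenuation
correction factor ACF = exp(+integral of mu) is >= 1; the survival
probability of a photon pair is 1/ACF.  The MLEM system model multiplies the
geometric projection by ``eps_i * eps_j * g / ACF``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CrystalMap
from .projdata import ProjData, bin_detector_lut
from .projector import forward_project, _luts
from .volume import VoxelVolume


def attenuation_factors(mu_map: VoxelVolume, cmap: CrystalMap,
                        template: ProjData, **ray_kw) -> ProjData:
    """ACF sinogram: ``exp(+integral of mu dl)`` along each LOR.

    Uses the same Siddon projector and geometry class as reconstruction, so
    attenuation correction is consistent with the system model.
    """
    line = forward_project(mu_map, cmap, template, **ray_kw)
    acf = template.copy_with(np.exp(line.values), geometry_class=cmap.geometry_class)
    return acf


def randoms_from_singles(singles_rates: np.ndarray, tau: float,
                         template: ProjData, duration: float = 1.0) -> ProjData:
    """Expected randoms counts per bin from per-crystal singles rates.

    The accidental-coincidence rate of a crystal pair (i, j) within a
    coincidence window ``tau`` is ``2 tau S_i S_j``; multiplied by the
    acquisition duration this gives expected counts.  Only non-rebinned
    templates are supported (rebin the result if needed).
    """
    if tau <= 0:
        raise ValueError("coincidence window must be positive")
    if np.any(np.asarray(singles_rates) < 0):
        raise ValueError("singles rates must be non-negative")
    if template.rebinned:
        raise ValueError("randoms are estimated on the 3-D bin structure")
    spec = template.spec
    R, N = spec.n_rings, spec.n_detectors_per_ring
    rates = np.asarray(singles_rates, dtype=float).reshape(R, N)
    dA, dB, valid = _luts(spec, template.tangential_size)
    rateA = rates[:, dA]                      # (R, V, T)
    rateB = rates[:, dB]
    out = 2.0 * tau * duration * rateA[:, None] * rateB[None, :]
    out *= valid[None, None]
    r = np.arange(R)
    ring_ok = np.abs(r[:, None] - r[None, :]) <= template.max_ring_diff
    out *= ring_ok[:, :, None, None]
    return template.copy_with(out)


# --------------------------------------------------------------------------
# component-based normalisation
# --------------------------------------------------------------------------

def _class_ids(template: ProjData):
    """Symmetry-class index per bin for the geometric normalisation factors.

    Bins are grouped by tangential index, ring difference (slice index for
    rebinned data) and the position of detector A within its block,
    exploiting the scanner's sector-fold symmetry (views are pooled).
    """
    spec = template.spec
    dA, dB, valid = _luts(spec, template.tangential_size)
    cpb = spec.crystals_per_block_trans
    posA = (dA % cpb).astype(np.int64)         # (V, T)
    T = template.tangential_size
    t_idx = np.arange(T, dtype=np.int64)
    if template.rebinned:
        S = template.values.shape[0]
        s_idx = np.arange(S, dtype=np.int64)
        key = ((s_idx[:, None, None] * T + t_idx[None, None, :]) * cpb
               + posA[None, :, :])
    else:
        R = spec.n_rings
        rd = np.abs(np.arange(R)[:, None] - np.arange(R)[None, :]).astype(np.int64)
        key = ((rd[:, :, None, None] * T + t_idx[None, None, None, :]) * cpb
               + posA[None, None, :, :])
    return np.ascontiguousarray(np.broadcast_to(key, template.values.shape))


def _crystal_index_arrays(template: ProjData):
    """Per-bin indices of the two participating 'crystals'.

    For 3-D data these are true crystal ids; for rebinned data efficiencies
    are tracked per transaxial detector (rings are folded by the rebinning).
    """
    spec = template.spec
    dA, dB, valid = _luts(spec, template.tangential_size)
    N = spec.n_detectors_per_ring
    if template.rebinned:
        S = template.values.shape[0]
        iA = np.broadcast_to(dA[None], template.values.shape)
        iB = np.broadcast_to(dB[None], template.values.shape)
        n_eff = N
    else:
        R = spec.n_rings
        r = np.arange(R)
        iA = r[:, None, None, None] * N + dA[None, None]
        iB = r[None, :, None, None] * N + dB[None, None]
        iA = np.broadcast_to(iA, template.values.shape)
        iB = np.broadcast_to(iB, template.values.shape)
        n_eff = R * N
    return np.ascontiguousarray(iA), np.ascontiguousarray(iB), n_eff


@dataclass
class NormFactors:
    """Crystal efficiencies and geometry-class factors from a uniform scan."""

    crystal_eff: np.ndarray               # (n_crystals,) or (n_det,) rebinned
    geometric: np.ndarray                 # (n_classes,) factors by class id
    class_ids: np.ndarray                 # per-bin class index (sinogram shape)
    crystal_A: np.ndarray                 # per-bin crystal indices
    crystal_B: np.ndarray

    def __post_init__(self):
        if np.any(self.crystal_eff <= 0) or np.any(self.geometric[self.geometric != 0] < 0):
            raise ValueError("normalisation factors must be strictly positive")

    def bin_efficiency(self) -> np.ndarray:
        """Combined per-bin efficiency eps_i * eps_j * g(class)."""
        return (self.crystal_eff[self.crystal_A] * self.crystal_eff[self.crystal_B]
                * self.geometric[self.class_ids])


def estimate_norm(measured_uniform: ProjData, model_uniform: ProjData,
                  n_outer: int = 10, scatter: ProjData | None = None,
                  randoms: ProjData | None = None) -> NormFactors:
    """Component-based normalisation by alternating multiplicative updates.

    Factorises the ratio measured/model of a uniform-cylinder scan into
    crystal efficiencies and geometric class factors, with count-weighted
    fan-sum updates (an EM-flavoured scheme).  Scatter and randoms estimates,
    if given, are subtracted from the measured data first (clamped at zero).
    Bins with zero model are excluded; efficiencies are normalised to mean 1.
    """
    m = measured_uniform.values.astype(float).copy()
    if randoms is not None:
        m -= randoms.values
    if scatter is not None:
        m -= scatter.values
    np.clip(m, 0.0, None, out=m)
    mod = model_uniform.values
    use = mod > 0

    cls = _class_ids(measured_uniform)
    iA, iB, n_eff = _crystal_index_arrays(measured_uniform)
    n_cls = int(cls.max()) + 1

    mf = m[use]
    modf = mod[use]
    clsf = cls[use]
    iAf = iA[use]
    iBf = iB[use]

    eps = np.ones(n_eff)
    g = np.ones(n_cls)
    for _ in range(max(1, n_outer)):
        pred = modf * eps[iAf] * eps[iBf]
        num = np.bincount(clsf, weights=mf, minlength=n_cls)
        den = np.bincount(clsf, weights=pred, minlength=n_cls)
        g = np.where(den > 0, num / np.maximum(den, 1e-30), 1.0)
        np.clip(g, 1e-6, None, out=g)

        pred_g = modf * g[clsf]
        numc = (np.bincount(iAf, weights=mf, minlength=n_eff)
                + np.bincount(iBf, weights=mf, minlength=n_eff))
        denc = (np.bincount(iAf, weights=pred_g * eps[iBf], minlength=n_eff)
                + np.bincount(iBf, weights=pred_g * eps[iAf], minlength=n_eff))
        eps = np.where(denc > 0, numc / np.maximum(denc, 1e-30), 1.0)
        np.clip(eps, 1e-6, None, out=eps)
        mean = eps.mean()
        eps /= mean
        g *= mean * mean
    return NormFactors(crystal_eff=eps, geometric=g, class_ids=cls,
                       crystal_A=iA, crystal_B=iB)


def norm_rms_residual(measured: ProjData, model: ProjData,
                      nf: NormFactors) -> float:
    """RMS of measured - model * bin_efficiency over usable bins."""
    use = model.values > 0
    pred = model.values * nf.bin_efficiency()
    return float(np.sqrt(np.mean((measured.values[use] - pred[use]) ** 2)))


@dataclass
class CorrectionSet:
    """Bundle of corrections consumed by MLEM.

    Any component may be None (treated as neutral).  ``multiplicative``
    returns the per-bin system-model coefficient ``eps_i eps_j g / ACF``;
    ``additive`` the expected background counts (randoms + scatter) in
    measured units.
    """

    norm: NormFactors | None = None
    acf: ProjData | None = None
    randoms: ProjData | None = None
    scatter: ProjData | None = None

    def __post_init__(self):
        if self.acf is not None and np.any(self.acf.values[self.acf.values != 0] < 1.0 - 1e-9):
            raise ValueError("ACF must be >= 1 everywhere")
        for name in ("randoms", "scatter"):
            obj = getattr(self, name)
            if obj is not None and np.any(obj.values < 0):
                raise ValueError(f"{name} must be non-negative")

    def multiplicative(self, template: ProjData) -> np.ndarray:
        c = np.ones_like(template.values)
        if self.norm is not None:
            c = c * self.norm.bin_efficiency()
        if self.acf is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                c = np.where(self.acf.values > 0, c / self.acf.values, 0.0)
        return c

    def additive(self, template: ProjData) -> np.ndarray:
        b = np.zeros_like(template.values)
        if self.randoms is not None:
            b = b + self.randoms.values
        if self.scatter is not None:
            b = b + self.scatter.values
        return b
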