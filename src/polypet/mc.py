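"""Monte Carlo coincidence simulator and the study phantoms.

A deliberately small stand-in for a full particle-transport code, keeping the
physics that matters for the geometry question: back-to-back 511 keV photon
pairs (no positron range, no non-colinearity), voxelised phantom attenuation
with Compton-only interactions sampled from the Klein-Nishina cross-section,
energy-dependent attenuation for down-scattered photons, volumetric detection
in the crystal layer (exponential interaction depth, so oblique photons can
penetrate into neighbouring crystals or escape), and a 425-650 keV energy
window on both photons of a prompt.  Coincidences are labelled true / scattered /
random, and per-crystal singles are tallied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from . import _kernels
from .geometry import CrystalMap, ScannerSpec, BLOCKS
from .projdata import (EVENT_DTYPE, EventList, LABEL_RANDOM, LABEL_SCATTERED,
                       LABEL_TRUE)
from .volume import VoxelVolume

MU_WATER_511 = 0.0096  # mm^-1

# water mass-attenuation ratios mu(E)/mu(511 keV); small built-in lookup
_E_TAB = np.array([60.0, 80.0, 100.0, 150.0, 200.0, 300.0, 400.0,
                   500.0, 511.0, 600.0, 700.0])
_MU_TAB = np.array([0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186, 0.1061,
                    0.09687, 0.09607, 0.08956, 0.08367])
MU_RATIO_TAB = _MU_TAB / _MU_TAB[_E_TAB == 511.0][0]


def mu_water_ratio(energy_kev) -> np.ndarray:
    """mu(E)/mu(511 keV) for water, linear interpolation on the lookup table."""
    return np.interp(energy_kev, _E_TAB, MU_RATIO_TAB)


@dataclass
class Phantom:
    """Aligned activity (arbitrary units/voxel) and 511 keV mu (mm^-1) maps."""

    activity: VoxelVolume
    mu_map: VoxelVolume
    rods: list = field(default_factory=list)   # layout table for IQ phantoms

    def __post_init__(self):
        if self.activity.dims != self.mu_map.dims:
            raise ValueError("activity and mu grids must be aligned")
        if np.any(self.activity.values < 0) or np.any(self.mu_map.values < 0):
            raise ValueError("activity and mu must be non-negative")


@dataclass
class SimConfig:
    """Simulation settings.

    ``positron_range`` and ``noncolinearity`` exist only to document that the
    emission model excludes them; enabling either is rejected.
    """

    n_annihilations: int = 1_000_000
    energy_window: Tuple[float, float] = (425.0, 650.0)
    rng_seed: int = 0
    duration: float = 1.0                # acquisition time (s), for rates
    positron_range: bool = False
    noncolinearity: bool = False
    energy_blur_frac: float = 0.0        # fractional Gaussian sigma, 0 = ideal
    randoms_rate: float = 0.0            # injected randoms per second
    energy_floor: float = 50.0           # stop tracking below this (keV)
    detector_mu: float = 0.087           # LYSO linear attenuation at 511 keV, mm^-1

    def __post_init__(self):
        if self.energy_window[0] >= self.energy_window[1]:
            raise ValueError("energy window low must be below high")
        if self.positron_range or self.noncolinearity:
            raise ValueError("positron range / non-colinearity are not modelled")


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

def make_point_source(offset_mm: float, spec: ScannerSpec,
                      total_activity: float = 1.0,
                      voxel_size: float = 0.5) -> Phantom:
    """Near-point source at ``(offset, 0, 0)``, axial centre, no attenuation.

    A single hot voxel of ``voxel_size`` mm emulates the point; 10 mm and
    100 mm transaxial offsets are the two standard resolution positions.
    """
    act = VoxelVolume.centred((1, 1, 1), voxel_size, centre=(offset_mm, 0.0, 0.0))
    act.values[0, 0, 0] = total_activity
    mu = act.like(fill=0.0)
    return Phantom(activity=act, mu_map=mu)


def make_uniform_cylinder(spec: ScannerSpec, radius_mm: float = 108.0,
                          length_mm: float | None = None,
                          voxel_size: float = 2.0,
                          activity_conc: float = 1.0,
                          mu_water: float = MU_WATER_511) -> Phantom:
    """Uniform water cylinder centred on the axis.

    Default radius 108 mm; the length extends through the whole axial field
    of view.  Voxels are classified by their centres.
    """
    if length_mm is None:
        length_mm = spec.axial_length
    n_t = int(math.ceil(2 * radius_mm / voxel_size)) + 2
    n_z = max(1, int(length_mm // voxel_size))
    act = VoxelVolume.centred((n_t, n_t, n_z), voxel_size)
    x, y, z = act.meshgrid()
    inside = np.broadcast_to((x * x + y * y) <= radius_mm ** 2, act.dims)
    act.values[:] = np.where(inside, activity_conc, 0.0)
    mu = act.like(np.where(inside, mu_water, 0.0))
    return Phantom(activity=act, mu_map=mu)


# image-quality rod layout: (diameter mm, kind); positions assigned on a ring
IQ_RODS = [(20.0, "air"), (15.0, "cold_water"), (12.0, "hot"),
           (9.0, "hot"), (6.0, "hot"), (4.5, "hot")]


def make_iq_phantom(spec: ScannerSpec, body_radius_mm: float = 90.0,
                    rod_circle_radius_mm: float = 52.0,
                    hot_ratio: float = 4.0, voxel_size: float = 2.0,
                    length_mm: float | None = None,
                    mu_water: float = MU_WATER_511) -> Phantom:
    """Image-quality phantom: hot/cold rods in a warm water background.

    Background activity 1; hot rods ``hot_ratio`` (4-to-1 by default); the
    cold water rod has no activity but water attenuation; the air rod has
    neither.  Rods sit every 60 degrees on a circle; the layout table is
    stored on the returned phantom.
    """
    if length_mm is None:
        length_mm = spec.axial_length
    n_t = int(math.ceil(2 * body_radius_mm / voxel_size)) + 2
    n_z = int(math.ceil(length_mm / voxel_size))
    act = VoxelVolume.centred((n_t, n_t, n_z), voxel_size)
    x, y, z = act.meshgrid()
    body = (x * x + y * y) <= body_radius_mm ** 2
    act.values[:] = np.where(body, 1.0, 0.0)
    mu_vals = np.where(body, mu_water, 0.0)
    rods = []
    for i, (diam, kind) in enumerate(IQ_RODS):
        ang = math.pi / 2 + i * math.pi / 3
        cx = rod_circle_radius_mm * math.cos(ang)
        cy = rod_circle_radius_mm * math.sin(ang)
        rod = ((x - cx) ** 2 + (y - cy) ** 2) <= (diam / 2) ** 2
        if kind == "hot":
            act.values[np.broadcast_to(rod, act.dims)] = hot_ratio
        elif kind == "cold_water":
            act.values[np.broadcast_to(rod, act.dims)] = 0.0
        else:  # air
            act.values[np.broadcast_to(rod, act.dims)] = 0.0
            mu_vals = np.where(rod, 0.0, mu_vals)
        rods.append({"diameter": diam, "kind": kind, "cx": cx, "cy": cy,
                     "ratio": hot_ratio if kind == "hot" else 0.0})
    mu = act.like(np.broadcast_to(mu_vals, act.dims).copy())
    return Phantom(activity=act, mu_map=mu, rods=rods)


# --------------------------------------------------------------------------
# physics helpers
# --------------------------------------------------------------------------

def compton_sample(e_in_kev: float, rng: np.random.Generator):
    """Draw one Compton scattering event: ``(E_out keV, polar angle rad)``.

    The deflection is sampled from the Klein-Nishina differential
    cross-section by rejection; the outgoing energy follows the Compton
    kinematics ``E' = E / (1 + (E/511)(1 - cos(theta)))``.
    """
    if e_in_kev <= 0:
        raise ValueError("photon energy must be positive")
    k = e_in_kev / 511.0
    while True:
        c = 1.0 - 2.0 * rng.random()
        ratio = 1.0 / (1.0 + k * (1.0 - c))
        f = ratio * ratio * (ratio + 1.0 / ratio - (1.0 - c * c))
        if rng.random() * 2.0 <= f:
            e_out = e_in_kev * ratio
            return e_out, math.acos(c)


# --------------------------------------------------------------------------
# scan simulation
# --------------------------------------------------------------------------

def simulate_scan(phantom: Phantom, cmap: CrystalMap, cfg: SimConfig) -> EventList:
    """Simulate a coincidence acquisition; fully reproducible from the seed.

    Every annihilation emits two exactly anti-parallel 511 keV photons from a
    position sampled proportional to activity.  Photons are tracked through
    the attenuation map (Compton only; the photoelectric fraction in water is
    negligible at these energies) and detected where their ray intercepts the
    crystal surface of the supplied map.  A prompt is recorded when both
    photons land in the energy window; it is labelled true when neither
    photon scattered.  Randoms can be injected at a configured rate by
    pairing independent singles.
    """
    spec = cmap.spec
    if spec.inter_block_gap != 0:
        raise NotImplementedError("simulation assumes gapless blocks")
    act = phantom.activity
    total = act.values.sum()
    if total <= 0:
        raise ValueError("phantom has no activity")
    hot = np.argwhere(act.values > 0)
    coords = np.abs(np.array(act.origin) + hot * np.array(act.voxel_size))
    extent = coords.max(axis=0) + np.array(act.voxel_size) / 2
    if (max(extent[0], extent[1]) > spec.effective_apothem
            or extent[2] > spec.axial_length / 2 + 1e-6):
        import warnings
        warnings.warn("phantom extends outside the scanner field of view")

    cdf = np.cumsum(act.values.ravel())
    cdf /= cdf[-1]
    n = int(cfg.n_annihilations)
    out_id1 = np.empty(n, dtype=np.int64)
    out_id2 = np.empty(n, dtype=np.int64)
    out_e1 = np.empty(n, dtype=np.float64)
    out_e2 = np.empty(n, dtype=np.float64)
    out_nc1 = np.empty(n, dtype=np.int64)
    out_nc2 = np.empty(n, dtype=np.int64)
    singles = np.zeros(spec.n_crystals, dtype=np.int64)

    amin = act.grid_min()
    mmin = phantom.mu_map.grid_min()
    det_mode = 1 if cmap.geometry_class == BLOCKS else 0
    if det_mode == 1:
        det_radius = spec.effective_apothem
    else:
        det_radius = float(np.hypot(cmap.centres[0, 0], cmap.centres[0, 1]))
    n_coinc = _kernels.mc_kernel(
        n, int(cfg.rng_seed) % (2 ** 31),
        cdf, act.dims[0], act.dims[1], act.dims[2],
        amin[0], amin[1], amin[2], *act.voxel_size,
        phantom.mu_map.values, mmin[0], mmin[1], mmin[2],
        *phantom.mu_map.voxel_size,
        _E_TAB, MU_RATIO_TAB, float(cfg.energy_floor),
        det_mode, spec.n_sectors, det_radius,
        spec.face_width / 2.0, spec.crystal_pitch_trans,
        spec.crystals_per_face_trans,
        -spec.axial_length / 2.0, spec.crystal_pitch_axial, spec.n_rings,
        float(spec.crystal_depth), float(cfg.detector_mu),
        float(cfg.energy_window[0]), float(cfg.energy_window[1]),
        out_id1, out_id2, out_e1, out_e2, out_nc1, out_nc2, singles)

    rec = np.zeros(n_coinc, dtype=EVENT_DTYPE)
    rec["id1"] = out_id1[:n_coinc]
    rec["id2"] = out_id2[:n_coinc]
    rec["e1"] = out_e1[:n_coinc]
    rec["e2"] = out_e2[:n_coinc]
    rec["nc1"] = out_nc1[:n_coinc]
    rec["nc2"] = out_nc2[:n_coinc]
    if cfg.energy_blur_frac > 0:
        rng = np.random.default_rng(cfg.rng_seed + 7)
        rec["e1"] = rec["e1"] * (1 + cfg.energy_blur_frac * rng.standard_normal(n_coinc))
        rec["e2"] = rec["e2"] * (1 + cfg.energy_blur_frac * rng.standard_normal(n_coinc))
        lo, hi = cfg.energy_window
        keep = ((lo <= rec["e1"]) & (rec["e1"] <= hi)
                & (lo <= rec["e2"]) & (rec["e2"] <= hi))
        rec = rec[keep].copy()
    rec["label"] = np.where(rec["nc1"] + rec["nc2"] > 0, LABEL_SCATTERED, LABEL_TRUE)

    if cfg.randoms_rate > 0:
        rng = np.random.default_rng(cfg.rng_seed + 13)
        n_rand = rng.poisson(cfg.randoms_rate * cfg.duration)
        if singles.sum() > 0 and n_rand > 0:
            p = singles / singles.sum()
            c1 = rng.choice(spec.n_crystals, size=n_rand, p=p)
            c2 = rng.choice(spec.n_crystals, size=n_rand, p=p)
            keep = (c1 % spec.n_detectors_per_ring) != (c2 % spec.n_detectors_per_ring)
            rrec = np.zeros(int(keep.sum()), dtype=EVENT_DTYPE)
            rrec["id1"], rrec["id2"] = c1[keep], c2[keep]
            rrec["e1"] = rrec["e2"] = 511.0
            rrec["label"] = LABEL_RANDOM
            rec = np.concatenate([rec, rrec])

    return EventList(spec=spec, records=rec, singles=singles,
                     duration=cfg.duration, seed=cfg.rng_seed)
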