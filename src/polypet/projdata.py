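"""Sinogram container, detector-pair <-> bin indexing, listmode binning, SSRB.

The bin convention is purely index-based and therefore identical for both
geometry interpretations of a scanner: the *same* event list binned once
serves reconstructions with either crystal map.

Interleaved convention (frozen)
-------------------------------
For transaxial detector indices ``d1 != d2`` on a ring of ``N`` detectors
(``N`` divisible by 4):

* ``sigma = (d1 + d2) mod N``; the view is ``v = sigma // 2`` (two detector
  sums per view -- the classic interleave).
* The pair is ordered so that ``delta = (dA - dB) mod N`` lies in
  ``[1, N/2]`` (ties at ``N/2`` are ordered smallest-index-first); the
  unsigned tangential index is ``|t| = N/2 - delta`` (0 for diametrically
  opposite detectors).
* The sign of ``t`` disambiguates the two pairs related by a half-turn of the
  scanner (which share ``sigma`` and ``delta`` but lie on opposite sides of
  the axis): it is the sign of the LOR's signed radial coordinate on the
  nominal equal-angle unit circle.

``ring1``/``ring2`` axes of the sinogram follow the rings of the ordered
detectors ``dA``/``dB``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .geometry import ScannerSpec, GEOMETRY_CLASSES

LABEL_TRUE, LABEL_SCATTERED, LABEL_RANDOM = 0, 1, 2
LABEL_NAMES = {LABEL_TRUE: "true", LABEL_SCATTERED: "scattered", LABEL_RANDOM: "random"}

EVENT_DTYPE = np.dtype([
    ("id1", np.int32), ("id2", np.int32),
    ("e1", np.float32), ("e2", np.float32),
    ("nc1", np.int16), ("nc2", np.int16),
    ("label", np.int8),
])


def _nominal_angles(d, spec: ScannerSpec):
    """Equal-angle detector azimuths used by the (geometry-free) bin convention."""
    cpf = spec.crystals_per_face_trans
    return (np.asarray(d, dtype=float) - (cpf - 1) / 2.0) * (2.0 * math.pi / spec.n_detectors_per_ring)


def _sign_on_unit_circle(dA, dB, spec: ScannerSpec):
    """Sign of the LOR's radial coordinate for nominal detector positions.

    The direction is folded into the upper half-plane (canonical ``dy > 0``,
    or ``dx > 0`` for horizontal lines) before taking the left-hand normal;
    this avoids the floating-point instability of an angle fold for LORs that
    are numerically horizontal.
    """
    aA = _nominal_angles(dA, spec)
    aB = _nominal_angles(dB, spec)
    dx = np.cos(aB) - np.cos(aA)
    dy = np.sin(aB) - np.sin(aA)
    eps = 1e-9
    flip = (dy < -eps) | ((np.abs(dy) <= eps) & (dx < 0))
    dx = np.where(flip, -dx, dx)
    dy = np.where(flip, -dy, dy)
    s = np.cos(aA) * (-dy) + np.sin(aA) * dx
    return np.where(np.abs(s) < 1e-12, 0.0, np.sign(s))


def pair_to_bin_arrays(d1, d2, spec: ScannerSpec):
    """Vectorised transaxial part of the pair -> bin mapping.

    Returns ``(view, tang, swapped)`` where ``swapped`` marks pairs whose
    canonical detector order is ``(d2, d1)``.  ``tang`` is the signed
    tangential index (window not applied here).
    """
    d1 = np.asarray(d1, dtype=np.int64)
    d2 = np.asarray(d2, dtype=np.int64)
    N = spec.n_detectors_per_ring
    if np.any(d1 == d2):
        raise ValueError("detector pair must use distinct transaxial positions")
    du = (d1 - d2) % N
    swapped = du > N // 2
    tie = du == N // 2
    swapped = np.where(tie, d1 > d2, swapped)
    dA = np.where(swapped, d2, d1)
    dB = np.where(swapped, d1, d2)
    delta = (dA - dB) % N
    sigma = (dA + dB) % N
    view = sigma // 2
    t_abs = N // 2 - delta
    sgn = _sign_on_unit_circle(dA, dB, spec)
    tang = (sgn * t_abs).astype(np.int64)
    return view, tang, swapped


def pair_to_bin(id1: int, id2: int, spec: ScannerSpec, tangential_size: int | None = None):
    """Map a crystal pair to ``(view, tangential, ring1, ring2)``.

    Raises ``ValueError`` for pairs outside the accepted tangential window
    (e.g. neighbouring detectors, whose LOR never crosses the field of view).
    """
    T = spec.n_detectors_per_ring * 3 // 4 if tangential_size is None else tangential_size
    N = spec.n_detectors_per_ring
    r1, d1 = divmod(int(id1), N)
    r2, d2 = divmod(int(id2), N)
    v, t, swapped = pair_to_bin_arrays(np.array([d1]), np.array([d2]), spec)
    v, t = int(v[0]), int(t[0])
    if abs(t) > T // 2 - 1:
        raise ValueError(f"pair ({id1},{id2}) outside tangential window (|t|={abs(t)})")
    if bool(swapped[0]):
        r1, r2 = r2, r1
    return v, t, r1, r2


def bin_to_pair(view: int, tang: int, ring1: int, ring2: int, spec: ScannerSpec):
    """Inverse of :func:`pair_to_bin` (crystal ids)."""
    N = spec.n_detectors_per_ring
    t_abs = abs(int(tang))
    delta = N // 2 - t_abs
    if not (1 <= delta <= N // 2) or not (0 <= view < N // 2):
        raise ValueError("bin outside sinogram")
    sigma = 2 * view if delta % 2 == 0 else 2 * view + 1
    dA = ((sigma + delta) // 2) % N
    dB = (dA - delta) % N
    if tang == 0:
        dA, dB = min(dA, dB), max(dA, dB)
    else:
        sgn = float(_sign_on_unit_circle(np.array([dA]), np.array([dB]), spec)[0])
        if sgn * tang < 0:
            dA = (dA + N // 2) % N
            dB = (dB + N // 2) % N
    return ring1 * N + dA, ring2 * N + dB


def bin_detector_lut(spec: ScannerSpec, tangential_size: int):
    """Per-(view, tangential) transaxial detector indices ``(dA, dB, valid)``.

    Rings factor out of the transaxial mapping, so one (V, T) table serves
    every ring pair.  Invalid entries (|t| = T/2, which the signed convention
    never produces) are masked.
    """
    N = spec.n_detectors_per_ring
    V, T = N // 2, tangential_size
    dA = np.zeros((V, T), dtype=np.int32)
    dB = np.zeros((V, T), dtype=np.int32)
    valid = np.zeros((V, T), dtype=bool)
    for v in range(V):
        for ti in range(T):
            t = ti - T // 2
            if abs(t) > T // 2 - 1:
                continue
            a, b = bin_to_pair(v, t, 0, 0, spec)
            dA[v, ti], dB[v, ti] = a, b
            valid[v, ti] = True
    return dA, dB, valid


@dataclass
class ProjData:
    """Sinogram container.

    ``values`` has shape ``(n_rings, n_rings, n_views, tangential_size)`` for
    3-D data (axes: ring of detector A, ring of detector B, view, tangential
    index offset by ``T//2``), or ``(n_slices, n_views, tangential_size)``
    after single-slice rebinning (``rebinned=True``).
    """

    spec: ScannerSpec
    values: np.ndarray
    geometry_class: str | None = None
    tangential_size: int = 0
    max_ring_diff: int | None = None
    rebinned: bool = False

    def __post_init__(self):
        if self.tangential_size == 0:
            self.tangential_size = self.values.shape[-1]
        if self.max_ring_diff is None:
            self.max_ring_diff = self.spec.n_rings - 1
        expected = self.shape_for(self.spec, self.tangential_size, self.rebinned)
        if tuple(self.values.shape) != expected:
            raise ValueError(f"values shape {self.values.shape} != expected {expected}")
        if self.geometry_class is not None and self.geometry_class not in GEOMETRY_CLASSES:
            raise ValueError(f"unknown geometry class {self.geometry_class!r}")

    @staticmethod
    def shape_for(spec: ScannerSpec, tangential_size: int, rebinned: bool = False):
        V = spec.n_detectors_per_ring // 2
        R = spec.n_rings
        if rebinned:
            return (2 * R - 1, V, tangential_size)
        return (R, R, V, tangential_size)

    @classmethod
    def zeros(cls, spec: ScannerSpec, tangential_size: int | None = None,
              geometry_class: str | None = None, max_ring_diff: int | None = None,
              rebinned: bool = False):
        T = spec.n_detectors_per_ring * 3 // 4 if tangential_size is None else tangential_size
        shape = cls.shape_for(spec, T, rebinned)
        return cls(spec=spec, values=np.zeros(shape), geometry_class=geometry_class,
                   tangential_size=T, max_ring_diff=max_ring_diff, rebinned=rebinned)

    @property
    def n_views(self) -> int:
        return self.spec.n_detectors_per_ring // 2

    def total(self) -> float:
        return float(self.values.sum())

    def copy_with(self, values: np.ndarray, **kw) -> "ProjData":
        args = dict(spec=self.spec, values=values, geometry_class=self.geometry_class,
                    tangential_size=self.tangential_size, max_ring_diff=self.max_ring_diff,
                    rebinned=self.rebinned)
        args.update(kw)
        return ProjData(**args)

    def slice_z(self) -> np.ndarray:
        """Axial positions of rebinned slices (mean ring-pair z)."""
        R = self.spec.n_rings
        ring_z = self.spec.ring_z(np.arange(R))
        z = np.zeros(2 * R - 1)
        cnt = np.zeros(2 * R - 1)
        for r1 in range(R):
            for r2 in range(R):
                z[r1 + r2] += (ring_z[r1] + ring_z[r2]) / 2.0
                cnt[r1 + r2] += 1
        return z / cnt


@dataclass
class EventList:
    """Labelled coincidence records plus per-crystal singles counts."""

    spec: ScannerSpec
    records: np.ndarray                       # EVENT_DTYPE
    singles: np.ndarray                       # (n_crystals,) counts
    duration: float = 1.0                     # acquisition time, s
    seed: int | None = None

    def __post_init__(self):
        if self.records.dtype != EVENT_DTYPE:
            raise ValueError("records must use the event dtype")
        if self.singles.shape != (self.spec.n_crystals,):
            raise ValueError("singles must have one entry per crystal")

    def __len__(self) -> int:
        return len(self.records)

    def counts_by_label(self) -> dict:
        lab = self.records["label"]
        return {name: int((lab == code).sum()) for code, name in LABEL_NAMES.items()}

    def select(self, label: int | None = None) -> "EventList":
        """Sub-list with a single label (e.g. trues only); singles kept."""
        if label is None:
            return self
        rec = self.records[self.records["label"] == label]
        return EventList(self.spec, rec.copy(), self.singles, self.duration, self.seed)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.records).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: ScannerSpec, singles=None, duration=1.0):
        df = pd.read_csv(path)
        rec = np.zeros(len(df), dtype=EVENT_DTYPE)
        for name in rec.dtype.names:
            rec[name] = df[name].to_numpy()
        if singles is None:
            singles = np.zeros(spec.n_crystals, dtype=np.int64)
        return cls(spec, rec, np.asarray(singles), duration)


def bin_events(events: EventList, spec: ScannerSpec | None = None,
               tangential_size: int | None = None, max_ring_diff: int | None = None,
               label: int | None = None) -> ProjData:
    """Histogram listmode coincidences into a sinogram.

    Events outside the tangential window or beyond ``max_ring_diff`` are
    rejected; the count is stored on the result as ``n_rejected``.  The
    mapping uses detector indices only and never the geometry class.
    """
    spec = events.spec if spec is None else spec
    events = events.select(label)
    out = ProjData.zeros(spec, tangential_size, max_ring_diff=max_ring_diff)
    T = out.tangential_size
    N = spec.n_detectors_per_ring
    rec = events.records
    if len(rec) == 0:
        out.n_rejected = 0
        return out
    r1, d1 = np.divmod(rec["id1"].astype(np.int64), N)
    r2, d2 = np.divmod(rec["id2"].astype(np.int64), N)
    # pairs in the same transaxial position (any rings) have no bin
    distinct = d1 != d2
    n_same = int((~distinct).sum())
    r1, d1, r2, d2 = r1[distinct], d1[distinct], r2[distinct], d2[distinct]
    v, t, swapped = pair_to_bin_arrays(d1, d2, spec)
    rA = np.where(swapped, r2, r1)
    rB = np.where(swapped, r1, r2)
    ok = (np.abs(t) <= T // 2 - 1) & (np.abs(rA - rB) <= out.max_ring_diff)
    ti = t[ok] + T // 2
    np.add.at(out.values, (rA[ok], rB[ok], v[ok], ti), 1.0)
    out.n_rejected = int((~ok).sum()) + n_same
    return out


def ssrb(data: ProjData) -> ProjData:
    """Single-slice rebinning: assign oblique sinograms to their mean-z slice.

    Slice index is ``ring1 + ring2`` (2R-1 slices); direct planes land on even
    slices unchanged.  Total counts are conserved exactly.  With non-zero
    inter-block gaps the mean axial position varies slightly within a slice;
    the grid ignores that (gaps default to zero).
    """
    if data.rebinned:
        raise ValueError("data is already rebinned")
    R = data.spec.n_rings
    out = ProjData.zeros(data.spec, data.tangential_size,
                         geometry_class=data.geometry_class, rebinned=True)
    for r1 in range(R):
        for r2 in range(R):
            if abs(r1 - r2) <= data.max_ring_diff:
                out.values[r1 + r2] += data.values[r1, r2]
    return out
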