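"""Scanner geometry: crystal maps for polygonal-prism and cylindrical interpretations.

A block PET scanner tiles rectangular crystal arrays onto the flat faces of a
polygonal prism (eight faces for the brain scanner modelled here).  Historically
reconstruction software approximates any ring scanner by *virtual* detectors
spread at equal angles on a cylinder.  Both interpretations of the *same*
physical scanner are built here as :class:`CrystalMap` objects sharing one
crystal numbering, so that a given detector pair can be traced with either set
of endpoint coordinates.  The mismatch between the two is the source of the
reconstruction artefacts this package demonstrates.

Coordinates are scanner-centred (mm): z along the scanner axis, origin at the
axial centre, z increasing toward the superior end.  Crystal numbering is
frozen: the transaxial index increases counter-clockwise starting on the face
that crosses the +x axis; the ring index counts from the -z end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

CYLINDRICAL = "Cylindrical"
BLOCKS = "BlocksOnCylindrical"
GEOMETRY_CLASSES = (CYLINDRICAL, BLOCKS)


@dataclass(frozen=True)
class ScannerSpec:
    """Parametric description of a polygonal block scanner.

    Defaults describe the octagonal brain scanner: 8 sectors, 4 transaxial x 5
    axial blocks per sector, 6 x 6 crystals per block at 4.1 mm pitch.  The
    apothem (axis-to-face distance) is not part of the published description;
    by default it is the smallest polygon whose faces hold the crystals
    edge-to-edge, ``face_width / (2 tan(pi/n_sectors))`` = 118.78 mm.
    """

    n_sectors: int = 8
    blocks_per_sector_trans: int = 4
    blocks_per_sector_axial: int = 5
    crystals_per_block_trans: int = 6
    crystals_per_block_axial: int = 6
    crystal_pitch_trans: float = 4.1
    crystal_pitch_axial: float = 4.1
    crystal_depth: float = 10.0
    inter_block_gap: float = 0.0
    apothem: float | None = None

    def __post_init__(self):
        for name in ("n_sectors", "blocks_per_sector_trans", "blocks_per_sector_axial",
                     "crystals_per_block_trans", "crystals_per_block_axial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("crystal_pitch_trans", "crystal_pitch_axial", "crystal_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.inter_block_gap < 0:
            raise ValueError("inter_block_gap must be >= 0")
        if self.apothem is not None and self.apothem <= 0:
            raise ValueError("apothem must be > 0")
        if self.n_detectors_per_ring % 4 != 0:
            raise ValueError("detectors per ring must be a multiple of 4 "
                             "(required by the interleaved sinogram convention)")

    # ---- derived quantities -------------------------------------------------
    @property
    def crystals_per_face_trans(self) -> int:
        return self.blocks_per_sector_trans * self.crystals_per_block_trans

    @property
    def n_detectors_per_ring(self) -> int:
        return self.n_sectors * self.crystals_per_face_trans

    @property
    def n_rings(self) -> int:
        return self.blocks_per_sector_axial * self.crystals_per_block_axial

    @property
    def n_crystals(self) -> int:
        return self.n_detectors_per_ring * self.n_rings

    @property
    def face_width(self) -> float:
        """Transaxial extent of one sector face occupied by crystals (mm)."""
        return (self.crystals_per_face_trans * self.crystal_pitch_trans
                + (self.blocks_per_sector_trans - 1) * self.inter_block_gap)

    @property
    def axial_length(self) -> float:
        return (self.n_rings * self.crystal_pitch_axial
                + (self.blocks_per_sector_axial - 1) * self.inter_block_gap)

    @property
    def effective_apothem(self) -> float:
        if self.apothem is not None:
            return self.apothem
        return self.face_width / (2.0 * math.tan(math.pi / self.n_sectors))

    @property
    def circumradius(self) -> float:
        return self.effective_apothem / math.cos(math.pi / self.n_sectors)

    def ring_z(self, ring: int | np.ndarray) -> np.ndarray:
        """Axial coordinate of a ring centre (mm); ring 0 at the -z end."""
        ring = np.asarray(ring)
        block = ring // self.crystals_per_block_axial
        z = (ring + 0.5) * self.crystal_pitch_axial + block * self.inter_block_gap
        return z - self.axial_length / 2.0

    # ---- YAML round trip ----------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScannerSpec":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("scanner spec YAML must be a mapping")
        if "scanner" in data:  # allow a nested config block
            data = data["scanner"]
        return cls(**data)


@dataclass
class CrystalMap:
    """Per-crystal front-face centre coordinates for one geometry interpretation.

    ``crystal_id = ring * n_detectors_per_ring + transaxial_index``.  The id
    assignment is identical for both geometry classes, so the same detector
    pair refers to the same bins regardless of interpretation.
    """

    spec: ScannerSpec
    geometry_class: str
    centres: np.ndarray            # (n_crystals, 3) mm
    inward_normals: np.ndarray     # (n_crystals, 3) unit vectors

    @property
    def n_crystals(self) -> int:
        return self.centres.shape[0]

    def crystal_id(self, ring, trans):
        return np.asarray(ring) * self.spec.n_detectors_per_ring + np.asarray(trans)

    def ring_and_trans(self, crystal_id):
        n = self.spec.n_detectors_per_ring
        cid = np.asarray(crystal_id)
        return cid // n, cid % n

    def positions_by_ring(self) -> np.ndarray:
        """Centres reshaped to (n_rings, n_detectors_per_ring, 3)."""
        return self.centres.reshape(self.spec.n_rings,
                                    self.spec.n_detectors_per_ring, 3)

    def to_dataframe(self) -> pd.DataFrame:
        ring, trans = self.ring_and_trans(np.arange(self.n_crystals))
        return pd.DataFrame({
            "crystal_id": np.arange(self.n_crystals),
            "ring": ring, "transaxial_index": trans,
            "x": self.centres[:, 0], "y": self.centres[:, 1], "z": self.centres[:, 2],
            "nx": self.inward_normals[:, 0], "ny": self.inward_normals[:, 1],
            "nz": self.inward_normals[:, 2],
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def virtual_cylinder_radius(spec: ScannerSpec) -> float:
    """Radius of the least-displacement virtual cylinder.

    The cylindrical interpretation spreads the crystals on a cylinder; the
    radius that moves them least from their true polygon-face positions is
    the mean radial distance of the block layout (the apothem would pull
    every off-centre crystal inward).
    """
    cpf = spec.crystals_per_face_trans
    j = np.arange(cpf)
    block = j // spec.crystals_per_block_trans
    u = ((j + 0.5) * spec.crystal_pitch_trans
         + block * spec.inter_block_gap) - spec.face_width / 2.0
    return float(np.hypot(spec.effective_apothem, u).mean())


def build_crystal_map(spec: ScannerSpec, geometry_class: str = BLOCKS,
                      cylinder_radius: float | None = None) -> CrystalMap:
    """Expand a scanner spec into per-crystal coordinates.

    BlocksOnCylindrical places crystals at equal pitch along each flat polygon
    face at distance ``apothem`` from the axis; Cylindrical places the same
    number of crystals at equal angular spacing on a virtual cylinder whose
    radius defaults to :func:`virtual_cylinder_radius` (override with
    ``cylinder_radius``).  Crystal ordering is identical in both maps.
    """
    if geometry_class not in GEOMETRY_CLASSES:
        raise ValueError(f"unknown geometry class {geometry_class!r}")
    n_det = spec.n_detectors_per_ring
    n_rings = spec.n_rings
    a = spec.effective_apothem

    ring_z = spec.ring_z(np.arange(n_rings))               # (R,)

    if geometry_class == BLOCKS:
        cpf = spec.crystals_per_face_trans
        sector = np.arange(n_det) // cpf
        j = np.arange(n_det) % cpf
        beta = 2.0 * math.pi * sector / spec.n_sectors      # face normal angle
        # in-face offset from the face midpoint, increasing counter-clockwise
        block = j // spec.crystals_per_block_trans
        u = ((j + 0.5) * spec.crystal_pitch_trans
             + block * spec.inter_block_gap) - spec.face_width / 2.0
        x = a * np.cos(beta) - u * np.sin(beta)
        y = a * np.sin(beta) + u * np.cos(beta)
        nx, ny = -np.cos(beta), -np.sin(beta)
    else:
        cpf = spec.crystals_per_face_trans
        r = virtual_cylinder_radius(spec) if cylinder_radius is None \
            else float(cylinder_radius)
        # equal angular spacing; face-0 centre maps to angle 0
        alpha = (np.arange(n_det) - (cpf - 1) / 2.0) * (2.0 * math.pi / n_det)
        x = r * np.cos(alpha)
        y = r * np.sin(alpha)
        nx, ny = -np.cos(alpha), -np.sin(alpha)

    centres = np.empty((n_rings * n_det, 3))
    normals = np.empty((n_rings * n_det, 3))
    centres[:, 0] = np.tile(x, n_rings)
    centres[:, 1] = np.tile(y, n_rings)
    centres[:, 2] = np.repeat(ring_z, n_det)
    normals[:, 0] = np.tile(nx, n_rings)
    normals[:, 1] = np.tile(ny, n_rings)
    normals[:, 2] = 0.0
    return CrystalMap(spec=spec, geometry_class=geometry_class,
                      centres=centres, inward_normals=normals)


def lor_endpoints(cmap: CrystalMap, id1: int, id2: int) -> Tuple[np.ndarray, np.ndarray]:
    """Front-face centres of a crystal pair (the LOR endpoints)."""
    if id1 == id2:
        raise ValueError("a LOR needs two distinct crystals")
    n = cmap.n_crystals
    for i in (id1, id2):
        if not (0 <= i < n):
            raise KeyError(f"unknown crystal id {i}")
    return cmap.centres[id1].copy(), cmap.centres[id2].copy()


def phi_of_lor(p1, p2) -> float:
    """Azimuthal angle of the LOR's transaxial direction, folded into [0, pi)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    if dx * dx + dy * dy < 1e-20:
        raise ValueError("purely axial line has no azimuthal angle")
    phi = math.atan2(dy, dx) % math.pi
    if phi >= math.pi:  # guard fp fold at exactly pi
        phi -= math.pi
    return phi


def s_vector(p1, p2) -> float:
    """Signed perpendicular distance from the scanner centre to the LOR.

    The magnitude is the 3-D point-to-line distance from the origin to the
    line through ``p1``, ``p2`` (computed by subtracting from ``-p1`` its
    projection on the line direction).  The sign follows the sinogram
    convention: positive when the perpendicular foot has a positive component
    along ``(-sin(phi), cos(phi), 0)`` where ``phi`` is the folded LOR azimuth.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    dd = float(d @ d)
    if dd < 1e-20:
        raise ValueError("coincident LOR endpoints")
    # perpendicular component of (p - p1) with p = origin
    perp = -p1 - (float(-p1 @ d) / dd) * d
    mag = float(np.linalg.norm(perp))
    # sign from the transaxial foot of the perpendicular; lines whose
    # transaxial projection passes through the axis get a positive sign
    s2d = _s_signed_2d(p1, p2)
    return math.copysign(mag, s2d) if s2d != 0.0 else mag


def _s_signed_2d(p1, p2) -> float:
    """Signed transaxial distance of the LOR's projection from the origin.

    The direction is folded into the upper half-plane before taking the
    left-hand normal (an exact fold; an angle fold is unstable for lines that
    are numerically horizontal).
    """
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    eps = 1e-9 * math.hypot(dx, dy)
    if dy < -eps or (abs(dy) <= eps and dx < 0):
        dx, dy = -dx, -dy
    norm = math.hypot(dx, dy)
    return (p1[0] * (-dy) + p1[1] * dx) / norm


def s_cylindrical_legacy(cmap: CrystalMap, id1: int, id2: int) -> float:
    """Legacy radial coordinate ``s = r sin(theta)``.

    Assumes the two detectors sit at equal angular spacing on a cylinder of
    radius ``r`` (the map's nominal radius), regardless of where the crystals
    actually are.  ``theta`` is the half-angle complement of the detectors'
    angular separation.  On a true cylinder this equals :func:`s_vector`; on a
    polygonal scanner it does not, which is the historical artefact source.
    Signed with the same convention as :func:`s_vector`.
    """
    if id1 == id2:
        raise ValueError("a LOR needs two distinct crystals")
    spec = cmap.spec
    n = spec.n_detectors_per_ring
    # "radius of scanner": the map's own mean crystal radius (equals the
    # virtual radius exactly for a Cylindrical map)
    r = float(np.hypot(cmap.centres[:n, 0], cmap.centres[:n, 1]).mean())
    _, d1 = cmap.ring_and_trans(id1)
    _, d2 = cmap.ring_and_trans(id2)
    cpf = spec.crystals_per_face_trans
    dalpha = 2.0 * math.pi / n
    a1 = (float(d1) - (cpf - 1) / 2.0) * dalpha
    a2 = (float(d2) - (cpf - 1) / 2.0) * dalpha
    # |s| = r cos(half angular separation); sign from the virtual endpoints
    half = (a1 - a2) / 2.0
    mag = abs(r * math.cos(half))
    p1 = np.array([r * math.cos(a1), r * math.sin(a1), 0.0])
    p2 = np.array([r * math.cos(a2), r * math.sin(a2), 0.0])
    s2d = _s_signed_2d(p1, p2)
    return math.copysign(mag, s2d) if s2d != 0.0 else 0.0
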