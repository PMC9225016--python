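"""Crystal map construction and LOR coordinate geometry."""

import math

import numpy as np
import pytest

from polypet import (BLOCKS, CYLINDRICAL, ScannerSpec, build_crystal_map,
                     lor_endpoints, phi_of_lor, s_cylindrical_legacy, s_vector,
                     virtual_cylinder_radius)


def brute_force_octagon_centres(spec):
    """Independent construction: place crystals face by face."""
    pts = []
    a = spec.effective_apothem
    cpf = spec.crystals_per_face_trans
    for sector in range(spec.n_sectors):
        beta = 2 * math.pi * sector / spec.n_sectors
        mid = np.array([a * math.cos(beta), a * math.sin(beta)])
        tang = np.array([-math.sin(beta), math.cos(beta)])
        for j in range(cpf):
            u = (j + 0.5) * spec.crystal_pitch_trans - spec.face_width / 2
            pts.append(mid + u * tang)
    return np.array(pts)


class TestBuildCrystalMap:
    def test_octagon_counts(self, brain_spec):
        assert brain_spec.n_detectors_per_ring == 192
        assert brain_spec.n_rings == 30
        assert brain_spec.n_crystals == 5760
        for gc in (BLOCKS, CYLINDRICAL):
            assert build_crystal_map(brain_spec, gc).n_crystals == 5760

    def test_square_scanner_faces_collinear_and_symmetric(self):
        spec = ScannerSpec(n_sectors=4, blocks_per_sector_trans=1,
                           blocks_per_sector_axial=1,
                           crystals_per_block_trans=2, crystals_per_block_axial=1)
        m = build_crystal_map(spec, BLOCKS)
        # sector 0 crosses +x: both crystals share x = apothem, symmetric in y
        c = m.centres[:2]
        assert np.allclose(c[:, 0], spec.effective_apothem)
        assert c[0, 1] == pytest.approx(-c[1, 1])

    def test_blocks_match_brute_force_construction(self, brain_spec, brain_blocks):
        ref = brute_force_octagon_centres(brain_spec)
        got = brain_blocks.centres[:192, :2]
        assert np.allclose(got, ref, atol=1e-9)
        # furthest crystal centres sit at the face ends
        dist = np.hypot(got[:, 0], got[:, 1])
        a = brain_spec.effective_apothem
        expected_max = math.hypot(a, brain_spec.face_width / 2
                                  - brain_spec.crystal_pitch_trans / 2)
        assert dist.max() == pytest.approx(expected_max, rel=1e-12)
        assert dist.max() < a / math.cos(math.pi / 8)  # below the corner radius

    def test_cylindrical_all_on_virtual_radius(self, brain_spec, brain_cyl):
        d = np.hypot(brain_cyl.centres[:, 0], brain_cyl.centres[:, 1])
        r = virtual_cylinder_radius(brain_spec)
        assert np.allclose(d, r)
        # the least-displacement radius lies between apothem and corner radius
        assert brain_spec.effective_apothem < r < brain_spec.circumradius
        # explicit override is honoured
        m = build_crystal_map(brain_spec, CYLINDRICAL, cylinder_radius=100.0)
        assert np.allclose(np.hypot(m.centres[:, 0], m.centres[:, 1]), 100.0)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            ScannerSpec(crystal_pitch_trans=-1)
        with pytest.raises(ValueError):
            ScannerSpec(n_sectors=0)

    def test_ordering_identical_between_classes(self, brain_blocks, brain_cyl):
        # same ids refer to the same physical crystal in either map: angular
        # order around the ring must agree
        ab = np.arctan2(brain_blocks.centres[:192, 1], brain_blocks.centres[:192, 0])
        ac = np.arctan2(brain_cyl.centres[:192, 1], brain_cyl.centres[:192, 0])
        assert np.allclose(np.unwrap(ab - ac), 0.0, atol=0.05)


class TestLorEndpoints:
    def test_opposite_crystals_same_ring(self, toy_blocks):
        spec = toy_blocks.spec
        N = spec.n_detectors_per_ring
        p1, p2 = lor_endpoints(toy_blocks, 0, N // 2)
        assert p1[2] == pytest.approx(p2[2])     # same ring, same z

    def test_swap_is_symmetric(self, toy_blocks):
        p1, p2 = lor_endpoints(toy_blocks, 3, 11)
        q1, q2 = lor_endpoints(toy_blocks, 11, 3)
        assert np.allclose(p1, q2) and np.allclose(p2, q1)

    def test_endpoints_on_declared_surface(self, brain_spec, brain_blocks, brain_cyl, rng):
        a = brain_spec.effective_apothem
        r_virt = virtual_cylinder_radius(brain_spec)
        ids = rng.integers(0, brain_spec.n_crystals, size=(50, 2))
        for i1, i2 in ids:
            if i1 == i2:
                continue
            for cmap in (brain_blocks, brain_cyl):
                for p in lor_endpoints(cmap, int(i1), int(i2)):
                    if cmap.geometry_class == CYLINDRICAL:
                        assert math.hypot(p[0], p[1]) == pytest.approx(r_virt)
                    else:
                        # distance to the nearest face plane is zero
                        betas = 2 * np.pi * np.arange(8) / 8
                        d = p[0] * np.cos(betas) + p[1] * np.sin(betas) - a
                        assert np.min(np.abs(d)) == pytest.approx(0, abs=1e-9)

    def test_unknown_id_and_degenerate(self, toy_blocks):
        with pytest.raises(KeyError):
            lor_endpoints(toy_blocks, 0, 10 ** 6)
        with pytest.raises(ValueError):
            lor_endpoints(toy_blocks, 5, 5)


class TestSCoordinate:
    def test_line_through_origin(self):
        assert s_vector((100, 0, 0), (-100, 0, 0)) == pytest.approx(0.0)

    def test_parallel_offset_line(self):
        assert abs(s_vector((100, 50, 0), (-100, 50, 0))) == pytest.approx(50.0)

    def test_cross_product_oracle(self, rng):
        for _ in range(200):
            p1 = rng.uniform(-150, 150, 3)
            p2 = rng.uniform(-150, 150, 3)
            if np.linalg.norm(p1[:2] - p2[:2]) < 1e-6:
                continue
            d = p2 - p1
            expected = np.linalg.norm(np.cross(d, p1)) / np.linalg.norm(d)
            assert abs(s_vector(p1, p2)) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            s_vector((1, 2, 3), (1, 2, 3))

    def test_rotation_invariance_of_magnitude(self, rng):
        p1 = np.array([120.0, 15.0, -4.0])
        p2 = np.array([-110.0, 42.0, 9.0])
        s0 = abs(s_vector(p1, p2))
        for ang in rng.uniform(0, 2 * math.pi, 10):
            c, s = math.cos(ang), math.sin(ang)
            rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            assert abs(s_vector(rot @ p1, rot @ p2)) == pytest.approx(s0, rel=1e-12)


class TestLegacyS:
    def test_diametric_pair_is_zero(self, brain_cyl):
        assert s_cylindrical_legacy(brain_cyl, 0, 96) == pytest.approx(0.0, abs=1e-9)

    @staticmethod
    def _transaxial(p):
        q = np.array(p, dtype=float)
        q[2] = 0.0
        return q

    def test_agrees_with_vector_s_on_cylinder(self, brain_cyl, rng):
        # the legacy formula is transaxial; compare against the vector s of
        # the endpoints projected onto the transaxial plane
        for _ in range(100):
            i1, i2 = rng.integers(0, 192, 2)
            if i1 == i2 or (i1 - i2) % 192 == 96:
                continue
            p1, p2 = lor_endpoints(brain_cyl, int(i1), int(i2))
            s_ref = s_vector(self._transaxial(p1), self._transaxial(p2))
            assert s_cylindrical_legacy(brain_cyl, int(i1), int(i2)) == \
                pytest.approx(s_ref, rel=1e-9, abs=1e-9)

    def test_differs_on_blocks(self, brain_blocks):
        diffs = []
        for i1 in range(0, 192, 7):
            for i2 in range(0, 192, 11):
                if i1 == i2:
                    continue
                p1, p2 = lor_endpoints(brain_blocks, i1, i2)
                s_true = s_vector(self._transaxial(p1), self._transaxial(p2))
                diffs.append(abs(s_cylindrical_legacy(brain_blocks, i1, i2)
                                 - s_true))
        assert max(diffs) > 1.0  # the artefact source: several-mm discrepancy


class TestPhi:
    @pytest.mark.parametrize("p1,p2,expected", [
        ((-50, 10, 0), (70, 10, 5), 0.0),
        ((3, -90, 0), (3, 80, -2), math.pi / 2),
    ])
    def test_axis_aligned(self, p1, p2, expected):
        assert phi_of_lor(p1, p2) == pytest.approx(expected, abs=1e-12)

    def test_fold_symmetry(self, rng):
        for _ in range(50):
            p1 = rng.uniform(-100, 100, 3)
            p2 = rng.uniform(-100, 100, 3)
            if np.linalg.norm(p1[:2] - p2[:2]) < 1e-6:
                continue
            assert phi_of_lor(p1, p2) == pytest.approx(phi_of_lor(p2, p1), abs=1e-12)

    def test_axial_line_rejected(self):
        with pytest.raises(ValueError):
            phi_of_lor((1, 1, 0), (1, 1, 50))


def max_s_discrepancy(n_sectors):
    """Largest |s_blocks - s_cylindrical| over a pair sample, fixed apothem."""
    spec = ScannerSpec(n_sectors=n_sectors, blocks_per_sector_trans=1,
                       blocks_per_sector_axial=1, crystals_per_block_trans=8,
                       crystals_per_block_axial=1, crystal_pitch_trans=4.0,
                       apothem=120.0)
    bl = build_crystal_map(spec, BLOCKS)
    cy = build_crystal_map(spec, CYLINDRICAL)
    worst = 0.0
    N = spec.n_detectors_per_ring
    for i1 in range(N):
        for i2 in range(i1 + 1, N):
            d1, d2 = lor_endpoints(bl, i1, i2)
            c1, c2 = lor_endpoints(cy, i1, i2)
            sb = s_vector(d1, d2)
            sc = s_vector(c1, c2)
            # near-horizontal chords may fold to opposite sign conventions
            # in the two maps; compare modulo the fold
            worst = max(worst, min(abs(sb - sc), abs(sb + sc)))
    return worst


def test_polygon_converges_to_cylinder():
    """The two interpretations disagree for few sectors and converge as the
    polygon approaches a cylinder."""
    d = [max_s_discrepancy(n) for n in (4, 8, 16)]
    assert d[0] > d[1] > d[2]
    assert d[1] > 0.5  # octagon-scale discrepancy is substantial (mm scale)
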