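"""Single scatter simulation, up-sampling, and tail fitting."""

import numpy as np
import pytest

from polypet import (BLOCKS, CYLINDRICAL, CorrectionSet, ProjData, ScannerSpec,
                     ScatterConfig, SimConfig, VoxelVolume,
                     attenuation_factors, bin_events, build_crystal_map,
                     estimate_scatter, make_uniform_cylinder,
                     mlem_reconstruct, simulate_scan, ssrb, sss,
                     sss_downsampled, tail_fit_scale, upsample_scatter,
                     LABEL_SCATTERED)
from polypet.projdata import pair_to_bin_arrays
from polypet.scatter import downsampled_spec


@pytest.fixture(scope="module")
def small_cylinder(toy_spec):
    return make_uniform_cylinder(toy_spec, radius_mm=40.0, voxel_size=5.0)


@pytest.fixture(scope="module")
def toy_cfg():
    return ScatterConfig(scatter_point_spacing=15.0)


class TestSss:
    def test_zero_activity(self, small_cylinder, toy_blocks, toy_cfg):
        act = small_cylinder.activity.like(fill=0.0)
        out = sss(act, small_cylinder.mu_map, toy_blocks, toy_cfg)
        assert np.all(out.values == 0)

    def test_empty_mu_support(self, small_cylinder, toy_blocks, toy_cfg):
        mu = small_cylinder.mu_map.like(fill=0.0)
        out = sss(small_cylinder.activity, mu, toy_blocks, toy_cfg)
        assert np.all(out.values == 0)

    def test_linearity_in_activity(self, small_cylinder, toy_blocks, toy_cfg):
        a = sss(small_cylinder.activity, small_cylinder.mu_map, toy_blocks,
                toy_cfg).values
        doubled = small_cylinder.activity.like(2 * small_cylinder.activity.values)
        b = sss(doubled, small_cylinder.mu_map, toy_blocks, toy_cfg).values
        assert np.allclose(b, 2 * a, rtol=1e-12)

    def test_mirror_symmetry(self, small_cylinder, toy_spec, toy_blocks, toy_cfg):
        """A phantom symmetric about the x-z plane gives a sinogram symmetric
        under the corresponding exact bin reflection."""
        out = sss(small_cylinder.activity, small_cylinder.mu_map, toy_blocks,
                  toy_cfg)
        N = toy_spec.n_detectors_per_ring
        cpf = toy_spec.crystals_per_face_trans
        T = out.tangential_size
        # mirror detector map: angle alpha -> -alpha
        def mirror(d):
            return (cpf - 1 - d) % N
        checked = 0
        for v in range(out.n_views):
            for ti in range(T):
                val = out.values[0, v, ti]
                if val <= 0:
                    continue
                from polypet import bin_to_pair
                t = ti - T // 2
                i1, i2 = bin_to_pair(v, t, 0, 0, toy_spec)
                vm, tm, _ = pair_to_bin_arrays(
                    np.array([mirror(i1 % N)]), np.array([mirror(i2 % N)]),
                    toy_spec)
                mval = out.values[0, int(vm[0]), int(tm[0]) + T // 2]
                assert mval == pytest.approx(val, rel=1e-6)
                checked += 1
        assert checked > 50

    def test_geometry_class_dependence(self, small_cylinder, toy_spec,
                                       toy_blocks, toy_cyl, toy_cfg):
        a = sss(small_cylinder.activity, small_cylinder.mu_map, toy_blocks,
                toy_cfg).values
        b = sss(small_cylinder.activity, small_cylinder.mu_map, toy_cyl,
                toy_cfg).values
        nz = a > 0
        assert np.max(np.abs(a[nz] - b[nz]) / a[nz]) > 0.0

    def test_energy_window_gates_angles(self, small_cylinder, toy_blocks):
        """A window just below 511 keV excludes forward scatter and leaves
        almost nothing (single scatter needs E' in the window)."""
        narrow = ScatterConfig(scatter_point_spacing=15.0,
                               energy_window=(100.0, 150.0))
        wide = ScatterConfig(scatter_point_spacing=15.0)
        lo = sss(small_cylinder.activity, small_cylinder.mu_map, toy_blocks,
                 narrow).values.sum()
        hi = sss(small_cylinder.activity, small_cylinder.mu_map, toy_blocks,
                 wide).values.sum()
        assert hi > 0 and lo < hi * 1e-6


class TestUpsample:
    def test_identity_when_same_sampling(self, toy_spec, rng):
        low = ProjData.zeros(toy_spec, rebinned=True,
                             geometry_class=CYLINDRICAL)
        low.values[:] = rng.random(low.values.shape)
        out = upsample_scatter(low, ProjData.zeros(toy_spec, rebinned=True))
        assert np.allclose(out.values, low.values, atol=1e-12)

    def test_constant_stays_constant(self, brain_spec):
        cfg = ScatterConfig()
        cspec = downsampled_spec(brain_spec, cfg)
        low = ProjData.zeros(cspec, rebinned=True, geometry_class=CYLINDRICAL)
        low.values[:] = 3.5
        out = upsample_scatter(low, ProjData.zeros(brain_spec, rebinned=True))
        assert np.allclose(out.values, 3.5)

    def test_blocks_legacy_path_narrows_profile(self, brain_spec):
        """Width-mismatch diagnostic: for blocks-tagged input the legacy
        up-sampler places the coarse grid 1:1 and the profile comes out
        visibly too narrow compared to the correctly stretched result."""
        cfg = ScatterConfig()
        cspec = downsampled_spec(brain_spec, cfg)
        low = ProjData.zeros(cspec, rebinned=True, geometry_class=BLOCKS)
        T_c = low.tangential_size
        t = np.arange(T_c) - T_c // 2
        prof = np.exp(-t ** 2 / (2 * 10.0 ** 2))
        low.values[:] = prof[None, None, :]
        target = ProjData.zeros(brain_spec, rebinned=True)
        legacy = upsample_scatter(low, target)
        low_cyl = low.copy_with(low.values, geometry_class=CYLINDRICAL)
        proper = upsample_scatter(low_cyl, target)
        from polypet import fwhm_1d
        w_legacy = fwhm_1d(legacy.values[30, 0], 1.0)
        w_proper = fwhm_1d(proper.values[30, 0], 1.0)
        assert w_legacy < w_proper


class TestTailFit:
    def _pair(self, spec, rng, scale=2.0, noise=False):
        est = ProjData.zeros(spec, rebinned=True)
        T = est.tangential_size
        t = np.arange(T) - T // 2
        edge = T // 3                       # "object" occupies the inner third
        est.values[:] = np.exp(-t ** 2 / (2 * (T / 7.0) ** 2))[None, None, :] * 30.0
        acf = est.copy_with(np.where(np.abs(t) > edge, 1.0, 3.0)
                            [None, None, :] * np.ones_like(est.values))
        measured_vals = est.values * scale
        if noise:
            measured_vals = rng.poisson(measured_vals).astype(float)
        measured = est.copy_with(measured_vals)
        return est, measured, acf

    def test_exact_ratio(self, toy_spec, rng):
        est, measured, acf = self._pair(toy_spec, rng, scale=2.0)
        out = tail_fit_scale(est, measured, acf,
                             ScatterConfig(tail_fit_per_slice=False))
        assert out.scale == pytest.approx(2.0, rel=1e-12)
        assert np.allclose(out.values, 2.0 * est.values)

    def test_no_tails_raises(self, toy_spec, rng):
        est, measured, acf = self._pair(toy_spec, rng)
        full = acf.copy_with(np.full_like(acf.values, 5.0))
        with pytest.raises(ValueError):
            tail_fit_scale(est, measured, full)

    def test_recovery_under_poisson_noise(self, brain_spec, rng):
        est, measured, acf = self._pair(brain_spec, rng, scale=1.7, noise=True)
        cfg = ScatterConfig(tail_fit_per_slice=False)
        tails = (acf.values < cfg.tail_threshold) & (est.values > 0)
        assert measured.values[tails].sum() > 1e5  # enough tail statistics
        out = tail_fit_scale(est, measured, acf, cfg)
        assert out.scale == pytest.approx(1.7, rel=0.05)

    def test_per_slice_scales_match_injected_profile(self, brain_spec, rng):
        est, measured, acf = self._pair(brain_spec, rng, scale=1.0)
        # modulate the measured data axially; per-slice fit must follow it
        S = est.values.shape[0]
        axial = 1.0 + 0.5 * np.sin(np.linspace(0, np.pi, S))
        measured = measured.copy_with(measured.values * axial[:, None, None])
        out = tail_fit_scale(est, measured, acf, ScatterConfig())
        assert np.allclose(out.slice_scales, axial, rtol=1e-9)

    def test_randoms_subtracted(self, toy_spec, rng):
        est, measured, acf = self._pair(toy_spec, rng, scale=1.0)
        randoms = est.copy_with(np.full_like(est.values, 5.0))
        bumped = measured.copy_with(measured.values + 5.0)
        out = tail_fit_scale(est, bumped, acf,
                             ScatterConfig(tail_fit_per_slice=False),
                             randoms=randoms)
        assert out.scale == pytest.approx(1.0, rel=1e-9)


@pytest.fixture(scope="module")
def study(brain_spec, brain_blocks):
    """A water-cylinder acquisition with its attenuation factors."""
    phantom = make_uniform_cylinder(brain_spec, voxel_size=2.0)
    events = simulate_scan(phantom, brain_blocks,
                           SimConfig(n_annihilations=8_000_000, rng_seed=5))
    prompts = ssrb(bin_events(events))
    acf = attenuation_factors(phantom.mu_map, brain_blocks, prompts)
    return dict(phantom=phantom, events=events, prompts=prompts, acf=acf,
                vol=VoxelVolume.centred((57, 57, 59), 4.0))


class TestEstimateScatter:
    def test_single_iteration_equals_one_pass(self, study, brain_blocks):
        cfg = ScatterConfig(scatter_point_spacing=20.0,
                            n_estimation_iterations=1)
        est = estimate_scatter(study["prompts"], study["acf"], None,
                               study["phantom"].mu_map, brain_blocks,
                               study["vol"], cfg, recon_iters=6)
        rec = mlem_reconstruct(study["prompts"], CorrectionSet(acf=study["acf"]),
                               brain_blocks, study["vol"], n_iter=6)
        one = tail_fit_scale(
            sss(rec, study["phantom"].mu_map, brain_blocks, cfg,
                tangential_size=study["prompts"].tangential_size),
            study["prompts"], study["acf"], cfg)
        assert np.allclose(est.values, one.values)
        assert np.all(est.values >= 0)

    def test_recovers_single_scatter_fraction(self, study, brain_blocks):
        """The estimated scatter fraction tracks the labelled single-scatter
        component of the simulation within 30% (the estimator models exactly
        one Compton interaction per prompt; multiple and double-photon
        scatters are outside its model)."""
        cfg = ScatterConfig(scatter_point_spacing=20.0,
                            n_estimation_iterations=2)
        est = estimate_scatter(study["prompts"], study["acf"], None,
                               study["phantom"].mu_map, brain_blocks,
                               study["vol"], cfg, recon_iters=6)
        rec = study["events"].records
        sc = rec[rec["label"] == LABEL_SCATTERED]
        n_single = int(((sc["nc1"] + sc["nc2"]) == 1).sum())
        sf_single = n_single / len(rec)
        sf_est = est.total() / study["prompts"].total()
        assert sf_est == pytest.approx(sf_single, rel=0.30)
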