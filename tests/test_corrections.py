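"""Attenuation, randoms, and component-based normalisation."""

import numpy as np
import pytest

from polypet import (CorrectionSet, ProjData, VoxelVolume, attenuation_factors,
                     bin_to_pair, estimate_norm, forward_project,
                     norm_rms_residual, randoms_from_singles)
from polypet.projector import _luts


class TestAttenuationFactors:
    def test_zero_mu_gives_unit_acf(self, toy_blocks, toy_spec):
        mu = VoxelVolume.centred((11, 11, 4), 4.0)
        acf = attenuation_factors(mu, toy_blocks, ProjData.zeros(toy_spec))
        assert np.allclose(acf.values, 1.0)

    def test_central_lor_closed_form(self, brain_blocks, brain_spec):
        """Diametral LOR through a uniform mu = 0.01/mm cylinder of radius
        50 mm: ACF = exp(0.01 x 100) = e."""
        mu = VoxelVolume.centred((121, 121, 21), 1.0)
        x, y, _ = mu.meshgrid()
        mu.values[:] = np.where(x ** 2 + y ** 2 <= 50.0 ** 2, 0.01, 0.0)
        tmpl = ProjData.zeros(brain_spec, max_ring_diff=0)
        acf = attenuation_factors(mu, brain_blocks, tmpl)
        # central bins (t=0) on the middle direct planes cross the full
        # 100 mm diameter (the mu slab covers |z| < 10.5 mm)
        T = tmpl.tangential_size
        centre = acf.values[14, 14, :, T // 2]
        assert np.max(centre) == pytest.approx(np.e, rel=0.02)
        assert np.min(centre) >= 1.0

    def test_consistent_with_forward_projection(self, toy_blocks, toy_spec, rng):
        mu = VoxelVolume.centred((11, 11, 4), 5.0)
        mu.values[:] = rng.random(mu.dims) * 0.01
        tmpl = ProjData.zeros(toy_spec)
        acf = attenuation_factors(mu, toy_blocks, tmpl)
        line = forward_project(mu, toy_blocks, tmpl)
        assert np.allclose(acf.values, np.exp(line.values), rtol=1e-12)

    def test_acf_at_least_one(self, toy_blocks, toy_spec, rng):
        mu = VoxelVolume.centred((11, 11, 4), 5.0)
        mu.values[:] = rng.random(mu.dims) * 0.02
        acf = attenuation_factors(mu, toy_blocks, ProjData.zeros(toy_spec))
        assert np.all(acf.values >= 1.0)


class TestRandoms:
    def test_direct_formula(self, toy_spec):
        """tau = 5 ns and 1e5 cps singles on both crystals -> 100 cps."""
        tmpl = ProjData.zeros(toy_spec)
        rates = np.full(toy_spec.n_crystals, 1e5)
        out = randoms_from_singles(rates, 5e-9, tmpl, duration=1.0)
        nz = out.values[out.values > 0]
        assert np.allclose(nz, 2 * 5e-9 * 1e10)
        assert nz[0] == pytest.approx(100.0)

    def test_zero_singles_crystal(self, toy_spec):
        tmpl = ProjData.zeros(toy_spec)
        rates = np.full(toy_spec.n_crystals, 1000.0)
        dead = 5
        rates[dead] = 0.0
        out = randoms_from_singles(rates, 5e-9, tmpl)
        dA, dB, valid = _luts(toy_spec, tmpl.tangential_size)
        N = toy_spec.n_detectors_per_ring
        for v in range(tmpl.n_views):
            for ti in range(tmpl.tangential_size):
                if not valid[v, ti]:
                    continue
                if dA[v, ti] == dead % N or dB[v, ti] == dead % N:
                    assert np.all(out.values[dead // N, :, v, ti] == 0) \
                        or np.all(out.values[:, dead // N, v, ti] == 0)

    def test_total_matches_pair_enumeration(self, toy_spec, rng):
        tmpl = ProjData.zeros(toy_spec)
        rates = rng.random(toy_spec.n_crystals) * 1e4
        tau, dur = 4e-9, 3.0
        out = randoms_from_singles(rates, tau, tmpl, duration=dur)
        # brute force over all crystal pairs accepted by the binner
        total = 0.0
        N = toy_spec.n_detectors_per_ring
        for v in range(tmpl.n_views):
            for t in range(-tmpl.tangential_size // 2 + 1,
                           tmpl.tangential_size // 2):
                for r1 in range(toy_spec.n_rings):
                    for r2 in range(toy_spec.n_rings):
                        i1, i2 = bin_to_pair(v, t, r1, r2, toy_spec)
                        total += 2 * tau * dur * rates[i1] * rates[i2]
        assert out.total() == pytest.approx(total, rel=1e-9)

    def test_invalid_inputs(self, toy_spec):
        tmpl = ProjData.zeros(toy_spec)
        with pytest.raises(ValueError):
            randoms_from_singles(np.full(toy_spec.n_crystals, 1.0), -1.0, tmpl)
        with pytest.raises(ValueError):
            randoms_from_singles(np.full(toy_spec.n_crystals, -1.0), 1e-9, tmpl)


@pytest.fixture(scope="module")
def uniform_model(toy_spec, toy_blocks):
    """Noise-free forward model of a uniform cylinder on the toy scanner."""
    act = VoxelVolume.centred((31, 31, 6), 4.0)
    x, y, _ = act.meshgrid()
    act.values[:] = np.where(x ** 2 + y ** 2 <= 50 ** 2, 1.0, 0.0)
    return forward_project(act, toy_blocks, ProjData.zeros(toy_spec))


class TestEstimateNorm:
    def test_identity_when_measured_equals_model(self, uniform_model):
        nf = estimate_norm(uniform_model, uniform_model, n_outer=5)
        assert np.allclose(nf.crystal_eff, 1.0, atol=1e-6)
        use = uniform_model.values > 0
        assert np.allclose(nf.bin_efficiency()[use], 1.0, atol=1e-6)

    def test_recovers_injected_crystal_efficiency(self, mid_spec, mid_blocks,
                                                  rng):
        """A crystal with efficiency 0.5 is recovered within 5% from a
        Poisson realisation at ~1e6 counts.  (Run on the mid-size scanner:
        on very small rings the geometric class factors partially absorb a
        single crystal's deficit.)"""
        act = VoxelVolume.centred((31, 31, 5), 2.5)
        x, y, _ = act.meshgrid()
        act.values[:] = np.where(x ** 2 + y ** 2 <= 30 ** 2, 1.0, 0.0)
        model = forward_project(act, mid_blocks, ProjData.zeros(mid_spec))
        scale = 1e6 / model.values.sum()
        model = model.copy_with(scale * model.values)
        eps_true = np.ones(mid_spec.n_crystals)
        eps_true[7] = 0.5
        eps_true[20] = 1.3
        iA, iB = _pair_indices(model)
        lam = model.values * eps_true[iA] * eps_true[iB]
        measured = model.copy_with(rng.poisson(lam).astype(float))
        nf = estimate_norm(measured, model, n_outer=10)
        ratio = nf.crystal_eff[7] / np.median(nf.crystal_eff)
        assert ratio == pytest.approx(0.5, rel=0.05)
        assert nf.crystal_eff[20] / np.median(nf.crystal_eff) == pytest.approx(1.3, rel=0.05)

    def test_fit_improves_with_outer_iterations(self, uniform_model, toy_spec, rng):
        eps_true = 1.0 + 0.3 * rng.standard_normal(toy_spec.n_crystals)
        eps_true = np.clip(eps_true, 0.4, None)
        iA, iB = _pair_indices(uniform_model)
        measured = uniform_model.copy_with(
            uniform_model.values * eps_true[iA] * eps_true[iB])
        rms = [norm_rms_residual(measured, uniform_model,
                                 estimate_norm(measured, uniform_model, n_outer=k))
               for k in (1, 3, 8)]
        assert rms[0] >= rms[1] >= rms[2]

    def test_norm_flattens_uniform_sinogram(self, uniform_model, toy_spec, rng):
        eps_true = np.clip(1 + 0.25 * rng.standard_normal(toy_spec.n_crystals),
                           0.3, None)
        iA, iB = _pair_indices(uniform_model)
        measured = uniform_model.copy_with(
            uniform_model.values * eps_true[iA] * eps_true[iB])
        nf = estimate_norm(measured, uniform_model, n_outer=8)
        use = uniform_model.values > 0
        raw = measured.values[use] / uniform_model.values[use]
        corrected = raw / nf.bin_efficiency()[use]
        assert corrected.std() / corrected.mean() < raw.std() / raw.mean()

    def test_factors_strictly_positive(self, uniform_model):
        nf = estimate_norm(uniform_model, uniform_model)
        assert np.all(nf.crystal_eff > 0)
        assert np.all(nf.geometric >= 0)


def _pair_indices(template):
    from polypet.corrections import _crystal_index_arrays
    iA, iB, _ = _crystal_index_arrays(template)
    return iA, iB


class TestCorrectionSet:
    def test_validation(self, toy_spec):
        bad = ProjData.zeros(toy_spec)
        bad.values[:] = 0.5
        with pytest.raises(ValueError):
            CorrectionSet(acf=bad)
        neg = ProjData.zeros(toy_spec)
        neg.values[0, 0, 0, 1] = -1
        with pytest.raises(ValueError):
            CorrectionSet(randoms=neg)

    def test_neutral_when_empty(self, toy_spec):
        tmpl = ProjData.zeros(toy_spec)
        cs = CorrectionSet()
        assert np.allclose(cs.multiplicative(tmpl), 1.0)
        assert np.allclose(cs.additive(tmpl), 0.0)
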