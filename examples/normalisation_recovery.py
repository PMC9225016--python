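"""Component-based normalisation: recover a known crystal-efficiency pattern
from a noisy uniform-cylinder scan.

A uniform cylinder's forward model is scaled by synthetic per-crystal
efficiencies and Poisson noise; the alternating crystal/geometric factor
estimate should recover the injected pattern to a few percent.
"""

import numpy as np

from polypet import (BLOCKS, ProjData, ScannerSpec, VoxelVolume,
                     build_crystal_map, estimate_norm, forward_project)
from polypet.corrections import _crystal_index_arrays

spec = ScannerSpec(n_sectors=8, blocks_per_sector_trans=1,
                   blocks_per_sector_axial=1, crystals_per_block_trans=6,
                   crystals_per_block_axial=2, crystal_pitch_trans=10.0,
                   crystal_pitch_axial=10.0)
cmap = build_crystal_map(spec, BLOCKS)

act = VoxelVolume.centred((31, 31, 6), 4.0)
x, y, _ = act.meshgrid()
act.values[:] = np.where(x ** 2 + y ** 2 <= 50 ** 2, 1.0, 0.0)
model = forward_project(act, cmap, ProjData.zeros(spec))
scale = 2e6 / model.values.sum()
model = model.copy_with(model.values * scale)

rng = np.random.default_rng(1)
eps_true = np.clip(1 + 0.2 * rng.standard_normal(spec.n_crystals), 0.5, None)
iA, iB, _ = _crystal_index_arrays(model)
measured = model.copy_with(
    rng.poisson(model.values * eps_true[iA] * eps_true[iB]).astype(float))

nf = estimate_norm(measured, model, n_outer=10)
err = np.abs(nf.crystal_eff / eps_true * eps_true.mean() - 1)
print(f"injected efficiencies in [{eps_true.min():.2f}, {eps_true.max():.2f}]")
print(f"recovery error: median {np.median(err) * 100:.1f}%, "
      f"max {err.max() * 100:.1f}%")
print("-> the crystal factors are recovered from the ratio measured/model; "
      "residual error reflects Poisson noise in the scan")
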