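"""Reconstruct a simulated uniform cylinder (trues only, no corrections) with
the accurate block geometry and with the legacy virtual-cylinder geometry.

The legacy model places the virtual detector ring on the polygon's inscribed
circle and misplaces every LOR radially, which prints a polygonal ring
pattern into the image.  The radial non-uniformity score (max/min of annulus
means inside r < 80 mm) quantifies it; without attenuation correction both
images are strongly cupped, so compare the two scores, not their absolute
size.  Expect a few minutes of runtime.
"""

from polypet import (BLOCKS, CYLINDRICAL, ScannerSpec, SimConfig, VoxelVolume,
                     bin_events, build_crystal_map, make_uniform_cylinder,
                     mlem_reconstruct, simulate_scan, ssrb, LABEL_TRUE)
from polypet.metrics import nonuniformity

spec = ScannerSpec()                          # 10 mm crystals, full scanner
blocks = build_crystal_map(spec, BLOCKS)
legacy = build_crystal_map(spec, CYLINDRICAL,
                           cylinder_radius=spec.effective_apothem)

phantom = make_uniform_cylinder(spec, voxel_size=2.0)
events = simulate_scan(phantom, blocks,
                       SimConfig(n_annihilations=30_000_000, rng_seed=4))
data = ssrb(bin_events(events, label=LABEL_TRUE))
print(f"binned {data.total():.0f} trues; rebinned to {data.values.shape[0]} slices")

vol = VoxelVolume.centred((115, 115, 59), 2.0)
for name, cmap in [("BlocksOnCylindrical", blocks), ("legacy Cylindrical", legacy)]:
    recon = mlem_reconstruct(data, None, cmap, vol, n_iter=40)
    score = nonuniformity(recon, r_max_mm=80.0, n_bins=16)
    print(f"{name:>20}: radial non-uniformity (max/min annulus means) = {score:.3f}")
print("-> the block map flattens the octagonal ring artefact: its radial "
      "profile varies less")
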