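"""Build the two interpretations of an octagonal block scanner and show how
far apart the radial LOR coordinate lands for the same detector pairs.

The block map places crystals on the flat faces of the octagonal prism; the
cylindrical map spreads the same crystals at equal angles on a virtual
cylinder.  The printed discrepancy is the root cause of the reconstruction
artefacts this package demonstrates.
"""

import numpy as np

from polypet import (BLOCKS, CYLINDRICAL, ScannerSpec, build_crystal_map,
                     lor_endpoints, s_cylindrical_legacy, s_vector)

spec = ScannerSpec()
print(f"scanner: {spec.n_detectors_per_ring} detectors/ring, "
      f"{spec.n_rings} rings, {spec.n_crystals} crystals, "
      f"apothem {spec.effective_apothem:.1f} mm")

blocks = build_crystal_map(spec, BLOCKS)
cyl = build_crystal_map(spec, CYLINDRICAL)
blocks.to_csv("blocks_crystal_map.csv")

from polypet import pair_to_bin

rng = np.random.default_rng(0)
diffs = []
while len(diffs) < 2000:
    i1, i2 = rng.integers(0, spec.n_detectors_per_ring, 2)
    if i1 == i2:
        continue
    try:  # only pairs whose LOR crosses the field of view
        pair_to_bin(int(i1), int(i2), spec)
    except ValueError:
        continue
    p1, p2 = lor_endpoints(blocks, int(i1), int(i2))
    p1[2] = p2[2] = 0.0                       # transaxial comparison
    s_true = s_vector(p1, p2)
    s_legacy = s_cylindrical_legacy(blocks, int(i1), int(i2))
    diffs.append(min(abs(s_true - s_legacy), abs(s_true + s_legacy)))
diffs = np.array(diffs)
print(f"|s_vector - s_legacy| over in-FOV detector pairs: "
      f"median {np.median(diffs):.2f} mm, max {diffs.max():.2f} mm")
print("-> the legacy cylindrical s-coordinate misplaces LORs radially by up")
print("   to about one crystal pitch; crystal map written to "
      "blocks_crystal_map.csv")
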