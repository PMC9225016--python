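# polypet

Most PET reconstruction software approximates the scanner as a ring of
detectors spread evenly on a cylinder.  Many real scanners — in particular
compact, organ-dedicated systems — are nothing of the sort: their crystals
tile the flat faces of a polygonal prism.  Feeding flat-face data to a
cylindrical geometry model misplaces the endpoints of every line of
response (LOR), and the error shows up as polygonal ring artefacts in
uniform objects, degraded point-spread functions near the edge of the field
of view, and scatter estimates with the wrong sinogram shape.

`polypet` is a desk-scale toolkit for measuring exactly those effects.  It
models one octagonal block scanner (8 sectors x 4 x 5 blocks of 6 x 6
crystals at 4.1 mm pitch) under both interpretations —
`BlocksOnCylindrical` (true flat faces) and `Cylindrical` (virtual
equal-angle ring) — with a single frozen crystal numbering, and carries
both through a complete chain:

* a Monte Carlo coincidence simulator (back-to-back 511 keV photons,
  Klein–Nishina Compton scattering in the phantom, volumetric crystal
  detection, 425–650 keV window, labelled trues/scattered/randoms);
* geometry-free interleaved sinogram binning, single-slice rebinning, and
  Interfile-style I/O;
* Siddon ray-tracing forward/back projection between the crystal positions
  of either map;
* corrections: attenuation factors `exp(+∫ mu dl)`, randoms from singles
  (`2 tau S_i S_j`), component-based normalisation (crystal efficiencies x
  geometric class factors);
* ordinary-Poisson MLEM with multiplicative and additive corrections;
* single scatter simulation on either geometry, with tail fitting and the
  (deliberately preserved, historically defective) coarse-grid up-sampler;
* image metrics: NEMA-style FWHM, ROI coefficient of variation, rod
  contrast, radial-profile artefact scores.

The sinogram bin for a detector pair depends only on detector *indices*,
never on the geometry class — so the same simulated event list can be
reconstructed under both interpretations and the difference is purely the
geometry model.  The radial LOR coordinate is computed from the endpoint
vectors, `s = |(p - p1) - ((p - p1)·d̂)d̂|` signed by the sinogram
convention; the legacy cylindrical shortcut `s = r sin(theta)` is kept as a
diagnostic (`s_cylindrical_legacy`) because its error *is* the artefact
under study.

## A worked example

```python
import numpy as np
import polypet as pp

spec   = pp.ScannerSpec(crystal_depth=1.0)          # thin crystals: no DOI
blocks = pp.build_crystal_map(spec, pp.BLOCKS)
cyl    = pp.build_crystal_map(spec, pp.CYLINDRICAL)

# a point source 100 mm off-axis, simulated once on the real geometry
phantom = pp.make_point_source(100.0, spec, voxel_size=0.2)
events  = pp.simulate_scan(phantom, blocks,
                           pp.SimConfig(n_annihilations=40_000_000, rng_seed=1))
data    = pp.bin_events(events, label=pp.LABEL_TRUE)   # ~2.1e5 trues

vol = pp.VoxelVolume.centred((41, 41, 41), 1.0, centre=(100.0, 0.0, 0.0))
for name, cmap in [("blocks", blocks), ("cylindrical", cyl)]:
    recon = pp.mlem_reconstruct(data, None, cmap, vol, n_iter=40)
    fx, fy, fz = pp.fwhm_3d(recon, around=(100.0, 0.0, 0.0))
    print(f"{name:>12}: FWHM x={fx:.2f} y={fy:.2f} z={fz:.2f} mm")
```

prints (seed 1):

```
      blocks: FWHM x=1.81 y=3.03 z=2.89 mm
 cylindrical: FWHM x=2.10 y=4.39 z=2.94 mm
```

The same coincidences, reconstructed with the wrong (cylindrical) detector
positions, smear the point tangentially (y) by almost one and a half
millimetres — the resolution penalty of mis-modelling a flat-faced scanner.
The `examples/` directory holds one short script per capability (geometry
discrepancies, this resolution study, the uniform-cylinder ring artefact,
the scatter-shape comparison, normalisation recovery).

## Command line

A thin CLI wires the pipeline for shell use:

```sh
polypet simulate --phantom cylinder --events 1e7 --seed 1 --out run/
polypet bin --config scanner.yaml --events run/events.csv --trues-only --rebin --out run/sino.hs
polypet recon --data run/sino.hs --geometry blocks --iters 40 --out run/img.hv
polypet analyze --volume run/img.hv --report uniformity
```

`simulate`, `bin`, `fwd`, `acf`, `norm`, `randoms`, `scatter`, `recon`,
`analyze` are available; one YAML config drives all, flags override, and
every run writes a manifest with its parameters and seeds.

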