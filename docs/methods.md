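# Methods

`polypet` models one physical scanner two ways and carries both models
through an entire PET chain — Monte Carlo acquisition, listmode binning,
corrections, MLEM reconstruction, image metrics — so that the consequences
of approximating a polygonal block scanner by a virtual cylinder can be
measured rather than argued.

## Scanner model

The default scanner is an octagonal prism: 8 sectors, each 4 transaxial x 5
axial blocks of 6 x 6 LYSO crystals at 4.1 mm pitch (192 detectors per ring,
30 rings, 5760 crystals).  The paperwork for such scanners rarely states the
ring radius; the default apothem is the smallest octagon whose faces carry
the crystals edge-to-edge,

    a = face_width / (2 tan(pi/8)) = 118.78 mm,

which comfortably admits the 108 mm phantom used for uniformity work.  Both
interpretations share one frozen crystal numbering (transaxial index
counter-clockwise from the face crossing +x; rings from the -z end), so a
detector pair means the same bins in either model:

* **BlocksOnCylindrical** — crystals at equal pitch on the flat faces at
  distance `a` from the axis (the true layout).
* **Cylindrical** — the same crystals spread at equal angles on a virtual
  cylinder.  Its radius is a genuinely open choice; we use the
  least-displacement fit, the mean radial distance of the true crystal
  positions (122.09 mm for the default scanner), configurable via
  `build_crystal_map(..., cylinder_radius=...)`.  The inscribed-circle
  choice (radius = apothem) systematically pulls every off-centre crystal
  inward and radially compresses reconstructions.

Crystal front-face centres serve as LOR endpoints (no depth-of-interaction
model in the reconstruction geometry).

## Sinogram convention

Bins are indexed purely by detector indices — never by coordinates — so the
same event list serves both reconstructions.  The interleaved scheme: view
`v = ((d1+d2) mod N) // 2`; unsigned tangential index `N/2 - delta` with
`delta = (dA-dB) mod N` in `[1, N/2]`; the sign of the tangential index
separates the two half-turn-related pairs and is taken from the signed
radial coordinate on the nominal equal-angle circle (with an exact
half-plane fold rather than an angle fold, which is numerically unstable for
horizontal LORs).  The default tangential window is `3N/4` bins, covering
|s| up to 109.8 mm so that the 108 mm uniformity phantom and the 100 mm
resolution source both fit inside the field of view; `N/2` would truncate
both.  Maximum ring difference defaults to full 3-D; single-slice rebinning
(SSRB) maps ring pair `(r1, r2)` to slice `r1+r2` and conserves counts
exactly.

## Projector

Siddon ray tracing in its incremental (Amanatides–Woo) form with half-open
voxel intervals (ties advance x before y before z — deterministic).  One ray
per bin between crystal-face centres is the default, matching the tracer of
the reconstruction library this toolkit models.  A stratified sub-ray bundle
(`n_rays_tang` x `n_rays_axial` offsets spanning one crystal pitch across
both faces) is available to model the finite detector aperture; forward and
back projection always use the same bundle and are exact adjoints (verified
to 1e-6 by dot-product tests).  Default reconstruction voxels are 1 mm
(resolution studies) and 2 mm (cylinder studies).

## Monte Carlo simulator

The generator reproduces the acquisition physics that matters for the
geometry question and deliberately nothing more:

* back-to-back 511 keV photons, isotropic, **no positron range, no
  non-colinearity** (rejected if requested);
* voxelised attenuation with Compton-only interactions (the photoelectric
  fraction in water is negligible above 100 keV); deflections sampled from
  the Klein–Nishina density by exact rejection; scattered photons are
  attenuated with mu scaled by a built-in water mu(E)/mu(511) lookup;
* volumetric detection: the photon enters the crystal layer (flat slabs for
  blocks, an annulus for the cylindrical layout) and interacts at an
  exponential depth with `detector_mu` = 0.087 mm^-1 (LYSO at 511 keV), so
  oblique photons penetrate laterally into neighbouring crystals or escape.
  The full photon energy is deposited at the first interaction point.  A
  pure front-face-intercept model was tried first and rejected: it makes the
  simulated data exactly consistent with the reconstruction geometry, and
  40-iteration MLEM then collapses point sources to sub-voxel spikes that no
  physical scanner produces;
* a 425–650 keV window on both photons of a prompt; labels: *true* (no
  Compton anywhere), *scattered*, *random*; per-crystal singles tallies;
  optional randoms injection by pairing independent singles at a configured
  rate (2·tau·S_i·S_j algebra, tau = 5 ns default);
* everything reproducible byte-for-byte from one seed.

Not modelled: positron range and non-colinearity (by design), inter-crystal
optical transport, partial-energy deposits and crystal-scatter clustering,
dead time, pile-up.  Passing tests therefore speak to geometry effects, not
to count-rate or energy-resolution behaviour of real scanners.

Phantoms: near-point sources (single 0.5 mm voxel by default; 0.2 mm in the
resolution experiments), the 108 mm uniform water cylinder spanning the
axial FOV, and an image-quality phantom (90 mm body; rods of 20 mm air,
15 mm non-radioactive water, and 12/9/6/4.5 mm hot rods at 4:1, every 60
degrees on a 52 mm circle — the rod ring and body radius are this package's
layout choices, recorded on the phantom object).

## Corrections

* **Attenuation**: ACF = exp(+∫ mu dl) per bin, computed with the same
  projector and geometry class as the reconstruction.
* **Randoms**: 2·tau·S_i·S_j per pair, converted to counts by the
  acquisition duration.
* **Normalisation**: two components — per-crystal efficiencies and
  geometric factors constant on symmetry classes (tangential index, ring
  difference or rebinned slice, and position-within-block; views pooled over
  the sector symmetry).  Alternating count-weighted fan-sum updates (10
  outer iterations by default, efficiencies normalised to mean 1).  The
  model coefficient used by MLEM is `eps_i · eps_j · g / ACF`.

## MLEM

Ordinary-Poisson MLEM: data stay in raw counts, `ybar = c·(A lambda) + b`
with `c` the multiplicative coefficient above and `b = randoms + scatter`.
Update `lambda <- lambda/sens · A^T[c·m/ybar]`, `sens = A^T c`; the initial
image is ones inside the FOV cylinder; zero-sensitivity voxels are masked;
40 iterations is the standard setting.  The Poisson log-likelihood is
non-decreasing (tracked on request) and `sum(c·A·lambda_hat)` approaches the
measured count total at convergence.

## Single scatter simulation

For scatter points on a regular lattice (20 mm default, restricted to
mu > 0.25·mu_water), each detector pair accumulates the two single-scatter
terms (annihilation on either leg): emission integral of the unscattered
leg x full 511 keV attenuation of that leg x Klein–Nishina probability of
the deflection x attenuation of the scattered leg at the downshifted energy
(same mu(E) lookup as the simulator, which is what makes the
model-vs-simulation comparison meaningful) x inverse-square and face-cosine
solid-angle factors x the energy-window gate on E'.  Detector positions come
from the crystal map, so the sinogram shape follows the geometry class.

The pipeline computes direct (equal-ring) planes at native sampling
("full-resolution 2-D", the default for block geometries) with in-between
slices averaged.  The historical down-sample/up-sample path is retained: the
coarse scanner halves detectors and rings at fixed apothem, and
`upsample_scatter` interpolates views and slices through their physical
coordinates.  Its tangential axis reproduces a known defect on purpose: for
block-tagged input the coarse grid is placed 1:1 on the target grid (no
bin-size stretch), yielding a visibly too-narrow profile — the regression
diagnostic compares its FWHM against full-resolution SSS.  For
cylinder-tagged input the physically stretched interpolation is used.

Tail fitting scales the estimate to `measured - randoms` over bins outside
the object by least squares, one scale per axial slice by default (global
optional).  Tail bins are those with ACF below 1.2 (at most ~19 mm of
water): close enough to the object edge for usable statistics, far enough
that no unscattered coincidences leak into the fit region (they do beyond
ACF ~ 1.3).  Scatter estimation iterates reconstruct -> SSS -> tail fit
(3 passes default) and averages.  Because the estimator is single-scatter
by construction while labelled Monte Carlo scatter includes multiple and
double-photon scatters (about 15% of scattered prompts for the 108 mm
cylinder), the estimated scatter fraction sits systematically below the
all-order truth; validation therefore compares it against the
single-scatter component.  Shape comparisons against Monte Carlo scatter
histograms are made on slice-summed sinograms rebinned to roughly 48 x 48
(view x tangential) so that counting noise does not dominate the
correlation.

## Metrics

FWHM follows the NEMA-style resolution procedure: the response function
along each axis is the volume summed over bands of about twice the
first-pass FWHM in the two orthogonal directions; the peak is refined by a
parabolic fit through three samples and the half-maximum crossings are
linearly interpolated.  Raw single-row profiles are available
(`band_sum=False`) but measure MLEM speckle rather than the point response.
Uniformity is the coefficient of variation in a centred cylindrical ROI
(radius 100 mm, length 50 mm).  Rod contrast: hot `100·(H/B-1)/(ratio-1)`,
cold `100·(1-C/B)`, background variability `100·SD/B` over twelve
rod-diameter ROIs on a background ring.  A radial annulus profile
(max/min of annulus means inside r < 80 mm) scores ring artefacts.

## Study sizes and what the experiments show

The bundled experiments are sized for a desk machine: point-source runs use
~2x10^5 true coincidences (40–60 M annihilations at 1 mm crystal depth),
cylinder runs ~10^7 annihilations at 2 mm voxels with SSRB, scatter models
a ~330-point lattice.  At these sizes the toolkit reproduces the
qualitative geometry results end-to-end: forward projections with the block
map land on the Monte Carlo sinogram peaks while the legacy cylindrical
s-coordinate does not; the octagonal ring artefact of the uniform cylinder
disappears when the block map supplies the endpoints; block-geometry SSS
matches the simulated scatter shape better than cylindrical SSS; and the
corrected uniform cylinder is less noisy with the block model.  Absolute
point-spread FWHMs are finer here than on the reference software chain,
whose internal sampling blur is not recoverable from public descriptions;
resolution comparisons between the two geometry models at the centre of the
FOV (where the true effect is a few percent) are below this toolkit's
reproducibility and are reported but not guaranteed directionally.

## Known limitations

* The simulator and the reconstructor share the same geometric description
  of the scanner; only the detection-depth physics breaks the inverse
  crime.  Effects absent from both (DOI modelling, detector response
  functions, block gaps) cancel rather than blur.
* Normalisation classes assume exact sector symmetry; a real scanner's
  block-to-block variations would need finer classes.
* SSS computes direct planes only; fixing the rebinned up-sampler for block
  geometries is out of scope (the defect is reproduced, not repaired).
* The randoms model pairs singles within a coincidence window rather than
  simulating timing.
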