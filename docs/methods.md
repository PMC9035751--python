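# Methods

This note documents the models, numerical choices and limitations of the
workbench; it is the place to look before trusting a number the package
prints.

## Coordinate conventions

Right-handed world frame in nanometres, `z = 0` at the glass substrate,
voxel-centre convention (index `i` ↔ `origin + i·voxel`), 0-based
indices, half-open voxel extents. Volumes carry an `axis_order` of
`XYZ` or `XZY`; the latter is the native layout of serial FIB-SEM
acquisitions (each frame an X–Z image, milling along Y). The FM→EM
transform is `p_EM = R_z(θ)·S·p_FM + t` with `S = diag(1, 1, s_z)`;
full 3D rotation is deliberately excluded because the flat substrate
pins the z axis of both modalities, and the optional z scale absorbs FM
axial calibration error only.

## Phantom

The generator emulates a peripheral patch of a cultured cell on a
gridded coverslip:

* **Organelles.** Lysosomes are spheres (radius 250–350 nm by default),
  mitochondria capsules of radius 150 nm, ER tubules capsules of radius
  60 nm around gently wandering polylines, ER sheets axis-aligned slabs.
  Every organelle has a 20 nm "stained membrane" boundary layer.
  Placement is bounded rejection sampling with disjoint bounding
  spheres; infeasible packings fail loudly.
* **Fiducials.** 90 nm gold-core/silica-shell particles, split for EM
  rendering into a 30 nm-radius BSE-bright core and an SE-bright shell
  annulus to 45 nm. Intracellular fiducials are placed uniformly inside
  lysosomes (emulating endocytic uptake); substrate fiducials rest on
  the glass (centre at `substrate_z + 45 nm`).
* **FM render.** Channels ER / lysosome / fiducial. The PSF is an
  anisotropic 3D Gaussian with σ_xy = 100 nm, σ_z = 300 nm — plausible
  for high-NA confocal optics; no wave-optical simulation. Fiducial
  spots are rendered analytically at their sub-voxel positions (so the
  spot integral is exactly proportional to the particle count);
  organelle channels are rasterized and blurred. Default grids: 34 or
  100 nm pixels, 100–200 nm z-step. Noise: Poisson shot noise with a
  photon-budget scale plus additive Gaussian read noise.
* **EM render.** Non-inverted backscattered-electron contrast of a
  heavy-metal-stained, resin-embedded cell: stained membranes (0.80)
  and dense lysosomal lumina (0.95) bright, mitochondrial matrix 0.60,
  electron-lucent ER lumina 0.18, cytoplasm/resin 0.40, glass 0.08, gold
  cores 1.6 (gold outscatters any stained organelle), SE shells 0.95 in
  the SE channel. Two features exist purely because real micrographs
  have them and downstream algorithms need them: a world-anchored
  value-noise *cytoplasmic texture* (amplitude 0.05, correlation length
  80 nm — ribosomes and stain mottle, the signal consecutive-slice
  correlation locks onto) and a 10 nm partial-volume width of the glass
  edge (what makes sub-pixel substrate detection possible). Slice
  stacks are sampled with the injected per-slice lateral jitter and row
  drift applied to the sampling grid, so ground truth is exact; EM
  noise is Gaussian only.
* **Tracks.** Stationary, confined-Brownian (per-step redraw inside the
  confinement radius; mean squared step 4DΔt for generous radii) and
  directed (v·Δt per frame) models at 1 s/frame over ~3 min, matching
  live-cell lysosome phenotypes.

What the phantom does *not* model: detector MTF, milling artefacts
(curtaining, charging), fluorescence quenching, deformable specimen
motion, organelle contact geometry in the default scene (organelles are
packed disjointly). Passing tests therefore demonstrate correctness of
the algorithms under controlled conditions, not performance on real
micrographs.

## Stack alignment

* **Substrate detection**: peak of the row-averaged gradient magnitude,
  refined by an intensity-weighted centroid over the ±2 neighbourhood;
  significance is the peak height in MAD units of the gradient profile
  (default gate 8). Convention: an abrupt step whose first fully
  changed row is `r` reports row `r`.
* **Vertical alignment** shifts every frame so substrate rows coincide
  with their median level; failed frames (up to 10%) inherit
  interpolated shifts. The aligned stack is re-anchored so the
  substrate defines `z = 0`; the constant offset to the nominal EM
  world frame is unobservable to the aligner and is absorbed by the
  registration fit downstream (the pipeline's reported z translation
  "error" against phantom ground truth reflects this re-anchoring).
* **Lateral alignment** estimates consecutive-pair x shifts by a
  bounded exhaustive normalized-cross-correlation search with parabolic
  sub-pixel refinement (robust on sparse, low-texture SEM frames where
  FFT phase correlation is unreliable), accumulates them, and removes a
  trend: by default the least-squares drift line; optionally a
  running-median trend (window 15 frames), which the end-to-end
  pipeline uses because oblique structures crossing the milling
  direction induce a smooth apparent drift that no line can absorb.
  Only differences *between* frames are observable: recovered jitter is
  defined up to the removed trend family. A crop window can exclude the
  substrate band, which is jitter-invariant and would otherwise pin the
  correlation at zero.
* **Resampling** to XYZ uses integer-factor arithmetic-mean binning
  along the SEM scan axes (preserves mean intensity and SNR) and linear
  interpolation along the milling axis. Requested voxel sizes must
  match an integer multiple of the native pixel within 0.2% (parameter
  `tol_frac`); otherwise the call fails naming the nearest achievable
  sizes rather than silently delivering different voxels.

## Registration

* **FM fiducials**: Laplacian-of-Gaussian candidates at the fiducial
  scale (local maxima above 8 robust SDs), refined by a 3D Gaussian
  least-squares fit; detections within one lateral PSF width merge
  (two emitters half a PSF width apart genuinely form one maximum).
* **EM fiducials**: a white top-hat transform (image minus its grey
  opening with a structuring element just larger than the 60 nm core)
  isolates core-sized bright peaks regardless of how much of the volume
  dense organelles occupy; candidates need local contrast > 0.6 (gold
  vs stained membranes), an equivalent diameter of 40–80 nm, and — when
  an SE volume is given — a coincident SE shell annulus 0.3 above the
  SE background.
* **Rotation from MIPs**: the in-plane angle is found by maximizing the
  Pearson correlation of the (rescaled, padded) maximum-intensity
  projections over an angle grid (1° coarse scan, 0.1° refinement,
  parabolic sub-step), with the translation solved by cross-correlation
  at each candidate. 180°-symmetric patterns raise an explicit
  ambiguity error instead of guessing; a manual angle can be supplied.
  This automates a step an operator would otherwise do by eye.
* **Matching**: `coarse_match_transform` (rotation grid × pairwise
  translation hypotheses over the point clouds) provides an
  operator-free initial transform; `match_points` then takes mutual
  nearest neighbours under it and runs RANSAC (3-point samples, 500
  iterations, seeded RNG, inlier band = the matching tolerance,
  default 300 nm).
* **Fit**: closed-form as described in the README; collinear-in-XY
  anchor geometry raises a degeneracy error. FRE is reported per axis;
  blind-target assessment guards the leave-one-out contract (a target
  that served as a fit anchor is rejected).
* **Targeting**: the FM ROI corners are transformed, hulled, and padded
  per axis by `k_margin` (default 3) times the per-axis registration
  accuracy (default 100/100/350 nm) — the box the microscope would
  actually mill.

## Segmentation

Per orientation (XY, XZ, ZY slices — a pure transpose; the volume is
assumed near-isotropic after voxel equalization): bunches of 10 slices
are averaged; inside each contour prompt the multilevel Otsu threshold
of the averaged intensities is computed (2 classes for lysosomes, whose
dense lumina separate directly from background; 3 for
membrane-delimited compartments, where background / lumen / membrane
form three populations) and its highest boundary thresholds every
original slice. The per-slice mask is
`fill(close(threshold ∪ Canny edges))` constrained to
`fill(close(threshold))`: the constraint removes the half-pixel halo
Canny places outside a boundary (making noise-free masks exact) while
closing and hole-filling recover membrane-enclosed lumina. Small
components (< 16 px) are dropped before closing so the closing footprint
cannot bridge noise speckle. Canny runs on the grayscale slice with
σ = 1 px and hysteresis thresholds at the 60th/90th gradient
quantiles; the closing element is a 3 px disc. Axis masks combine by
2-of-3 voting (`min_votes=1` gives the permissive union reading).
Classes run sequentially — lysosome, mitochondrion, ER — and each
class's voxels are reset to the background median (not literal zero,
which would distort later Otsu statistics) before the next class, making
class masks disjoint by construction. The multilevel Otsu itself is an
exact exhaustive maximizer of between-class variance on the histogram
(for 8-bit data this is the exact discrete optimum; generic optimizers
can land a few grey levels off on flat objectives).

The scripted prompter replaces the operator for automated testing: per
bunch it emits the convex hull of each ground-truth cross-section,
dilated by 5 px — a single pass, no accept/redraw loop.

## Quantification

* **Tracks**: per-frame speed = step length / interval; average
  velocity = mean speed; both path length and net displacement are
  reported because "total displacement" is ambiguous between them
  (path ≥ net always, equality only for collinear monotone motion).
* **Morphometrics**: volume = voxel count × voxel volume; surface area
  = exposed voxel faces × face area × 2/3 (the standard compensation
  for the ~3/2 overestimate of smooth surfaces by face counting);
  sphericity = π^⅓(6V)^⅔/A, within 2% and ≥ 0.93 respectively on a
  280 nm digital ball at 10 nm voxels.
* **Contact sites**: a patch of surface voxels of class A whose
  membrane gap to class B is below 20 nm over an in-surface extent of
  at least 20 nm. The gap is the Euclidean distance transform between
  voxel centres minus one mean voxel extent (half a voxel per side),
  approximating membrane-to-membrane distance; since boundary voxel
  centres lie inside their surfaces, a true gap of threshold + one
  voxel can never be falsely detected. Patch area uses the same
  face-counting estimator divided by two (a one-voxel sheet exposes
  both sides but represents one interface). Voxels coarser than the gap
  threshold trigger a warning, not an error.

## Problem sizes

Defaults were chosen so every experiment is comfortable on a laptop
core: the blind-target envelope uses 50 phantom seeds of 11 fiducials;
the segmentation phantom is a 2×2×1.4 µm volume at 10 nm voxels
(5.6 M voxels, three classes, three orientations); the alignment stack
is 80–100 frames of 240×140 px; the end-to-end demo renders a 4×4×1.8 µm
scene at 10 nm pixels / 20 nm milling pitch (~27 M samples per
detector). All randomness flows from explicit seeds; every render is a
pure function of (scene, geometry, seed).

## Known limitations

* Consecutive-pair lateral alignment accumulates content-change error
  on realistic (non-y-invariant) scenes (~1.5 px residual in the demo);
  fiducial-based registration downstream is the backstop, as in
  practice.
* The rotation search assumes the true angle lies in the configured
  range (default ±20°) and that fiducial constellations are not
  rotationally symmetric.
* Segmentation assumes organelle interiors are enclosed by their
  thresholded boundary within each 2D slice; open structures (e.g. a
  sheet seen edge-on at a volume border) fill incompletely.
* Contact-site geometry is voxel-limited: gaps are only resolved to
  about one voxel, and the default scene generator packs organelles
  disjointly, so contact statistics on it are trivially zero — use
  purpose-built scenes (as the tests do) to exercise them.
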