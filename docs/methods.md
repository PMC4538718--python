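# Methods

This note records the models, parameter choices and limitations behind
`petasbench`, in the order data flows through the package.

## Digital phantom model

A phantom is a fine-grid **uptake template**: a non-negative relative-activity
volume on a 1 × 1 × 2 mm grid.  The 2-mm axial pitch mirrors the slice
spacing of stacked printed-sheet phantoms, and the in-plane 1 mm pitch keeps
the ground truth well above the PET resolution; both are configurable
(`GridSpec`).  The background is 1.0 everywhere, optionally overwritten by
ellipsoidal or cuboidal structures carrying other constant levels (painted
in list order, later structures winning, with a warning on overlap).

Lesions are described declaratively (`LesionSpec`): a shape (sphere by
diameter; spheroid or irregular shape by target volume in mL), an uptake
pattern, a tumour-to-background ratio (TBR, default 4 — the ratio used for
all heterogeneous-lesion experiments; no TBR is published for the two-level
sphere battery, so the same value is used there for comparability), and a
centre.  Against the local background level `B` (mean background under the
lesion footprint), the patterns are:

* **homogeneous** — `TBR·B` everywhere inside.
* **two_level** — low rim `L = TBR·B` and a concentric central high region
  `H = 2L − B`, so the two contrast steps are equal (`H − L = L − B`
  exactly on the template).  The high region is a scaled copy of the outer
  shape with linear factor 0.5 (half the diameter, one eighth of the
  volume); the central region's size is not published, so the factor is a
  parameter.
* **gaussian** — background plus the homogeneous excess smoothed with a
  Gaussian kernel, modelling centrally peaked uptake.  Default kernel FWHM:
  half the equivalent diameter (unpublished; parameter).
* **necrotic** — homogeneous with a concentric core reset to `B` (zero
  excess).  The core holds 40 % of the lesion volume by default
  (unpublished; parameter).  The core level equals the background rather
  than zero because, in measured images of such phantoms, the necrotic
  region reads background-like intensity through noise and spill-in; a
  template core at `B` reproduces that image-level behaviour directly and
  keeps the lowest-intensity cluster of the clustering methods anchored to
  background + core.
* **necrotic_gaussian** — the necrotic excess, Gaussian smoothed.  Default
  kernel FWHM: a quarter of the equivalent diameter — the half-diameter
  kernel used for the `gaussian` pattern would fill the cold core in
  completely (the smoothed annulus then peaks at the centre), erasing the
  annular pattern this case exists to model.

**Ground truth.**  `lesion_mask` is always the full outer shape.  For
necrotic patterns the *delivered* ground truth excludes the core (the
metabolically active volume is the annulus); the outer shape and the core
are retained separately so sensitivity analyses under the alternative
convention remain possible.

**Rasterisation.**  Analytic shapes are binarised by sub-voxel coverage
sampling (4 × 4 × 6 sub-samples) followed by volume matching: voxels are
ranked by covered fraction and the top `round(Σ fractions)` kept.  This
bounds the volume error by half a voxel irrespective of how a shape aligns
with the anisotropic grid; a plain ≥ 0.5 majority rule can be several
percent off for a 13-mm sphere on 2-mm slices.  Measured errors for the
sphere battery are ≤ 0.2 %.

**Irregular shapes.**  A star-shaped surface: a sphere whose radius is
modulated by a seeded random real spherical-harmonic series (degree ≤ 4,
amplitude 0.3 of the base radius, clipped at 0.25), volume-rescaled to the
target (first analytically via the solid-angle integral of `R³`, then
iteratively against the rasterised volume to within 5 %).  The construction
is connected by design, deterministic per seed, and markedly non-spherical
(sphericity ≈ 0.74 for seed 1 at 11 mL).  It stands in for a manually
delineated clinical outline, which cannot be shipped.

## Scanner model

`simulate_pet` models acquisition + reconstruction as three steps:

1. **Exact partial-volume resampling** onto the PET grid (default
   2.73 × 2.73 × 3.27 mm, co-centred with the template).  Each PET voxel
   reads the mean template activity over its box, computed by separable
   box-overlap integration — a constant field stays exactly constant, and
   integrated activity over the covered region is conserved exactly.
2. **Isotropic Gaussian blur**, default FWHM 6.4 mm with edge-replicating
   padding.  Only the reconstruction post-filter cut-off is published for
   the protocol modelled; scanner intrinsic resolution is folded into the
   single kernel, which therefore slightly *understates* total blur.
   Measured point-source FWHM on the PET grid is ~7.8 mm (kernel ⊗ voxel).
3. **Poisson noise**: counts drawn per voxel with mean
   `noise_scale × blurred value`, divided back by `noise_scale`.  The
   default 500 counts per unit background intensity per voxel gives ~4.5 %
   relative noise in the background — visually realistic speckle for a
   clinical whole-body protocol; the source experiments do not characterise
   image noise, so this is a package choice.  `noiseless=True` disables it;
   a fixed `noise_seed` makes runs bit-reproducible.

Sinogram-level reconstruction (ML-OSEM/TOF), attenuation, scatter and the
plastic-sheet physics of a real sandwich phantom are out of scope.

Printout export writes one grey-level page (values linearly scaled to
[0, 1]) per 2-mm slice on a 168 × 197 mm page with cross-shaped T/L/R
alignment markers 20 mm outside the pattern's bounding box.  Marker
localisation finds, per slice, the hottest voxel in a 5 × 5 window around
the expected position (ties to the lowest linear index, flat windows
flagged low-confidence) and reports offsets against the per-marker mean
position and against the expected position.

## Printer calibration

Grey level → deposited ink is fitted as a least-squares cubic over all
replicates (≥ 5 distinct grey levels required); ink × activity → counts as
a pooled least-squares line.  Both fits report R² and the cubic must be
monotone non-decreasing on the sampled range, otherwise an error asks for
denser sampling.  Decay correction is `counts · 2^(Δt / T½)` with
T½ = 109.77 min (¹⁸F).  The grey level for a requested relative activity
inverts the composed response `counts(grey)` — normalised to its value at
the top of the grey domain, since the phantom models uptake *ratios* —
by bisection to 10⁻⁶ in grey; the closed-form cubic inverse is avoided
because the composed cubic-in-linear form is simpler and safer to bracket.
Round-trip error is below 10⁻⁵.

## Segmentation methods

All methods receive the ROI: the ground-truth bounding box dilated by
`ceil(10 mm / spacing)` voxels per axis.  The background level is the mean
of the ROI box's one-voxel outer shell.  Connectivity is 26-neighbour in
3-D, 8-neighbour in 2-D.  The automatic seed is the maximum of the
3 × 3 × 3-mean-smoothed ROI (ties: brightest raw voxel, then lowest linear
index).

* **AT** — iterate `T = bg + β·(mean-in-mask − bg)` from the half-max mask
  until fixed point (β = 0.5, cap 100 iterations); deliver the largest
  connected component of the super-threshold set.  No hole-fill: annular
  lesions stay annular.
* **RG** — grow the connected component of `{v ≥ α · region-mean}` around
  the seed for a decreasing α schedule (0.95 → 0.2, step 0.025).  Regions
  reaching the ROI border have flooded into the background and are
  discarded; among the rest, the largest region whose relative volume
  growth is within 2 % of the slowest observed growth is kept (the stable
  plateau at the lesion boundary).  The mask is hole-filled, which is what
  makes single-seed region growing engulf necrotic cores.
* **GCM2–GCM8** — fuzzy C-means (fuzziness 2) on raw voxel intensities,
  deterministic quantile initialisation, per-class Gaussian mean/variance
  re-estimated each sweep and reported as diagnostics.  Plain intensity
  distance is used for the memberships: likelihood-normalised variants let
  the broad tumour class swallow the narrow, heavily populated background
  mode of a PET ROI, inverting the background-cluster rule.  After
  defuzzification the lowest-mean cluster is background and the union of
  the others is tumour (largest component, hole-filled).
* **WT** — 2-D by design, per axial slice: optional smoothing (default
  none — the input is already post-filtered), Sobel gradient magnitude,
  marker-based watershed with the internal marker the connected
  high-intensity region (≥ bg + 0.5·(max − bg)) containing the in-slice
  maximum and external markers the slice border plus low-intensity pixels
  (≤ bg + 0.25·(max − bg)).  Slices without an internal marker, or whose
  internal basin is smaller than 2 pixels, are omitted; the stacked result
  keeps its largest 3-D component, unfilled.

The AT update rule, RG growth/stopping criterion, GCM membership coupling
and WT marker rules are not published for the methods this benchmark
mirrors; the rules above are this package's own parameter-light choices,
selected to reproduce the documented qualitative behaviours (clustering
sensitivity rising and precision falling with cluster count; region
growing enclosing, and thresholding/watershed excluding, necrotic cores;
binary methods losing sensitivity on strongly heterogeneous spheres).

## Evaluation and study design

Metrics are computed voxel-wise on the PET grid with no sub-voxel
interpolation.  An empty segmentation is recorded as a zero-metric failure
row at the study level (the individual metric functions still raise).  The
DSC error bar is ±4 % of (1 − DSC), reflecting that accurate methods are
least sensitive to setup errors; DSC > 0.7 (strict) flags good overlap.

The default battery mirrors the physical study: six two-level spheres
(all ten methods), the 11 mL spheroid under four patterns and the irregular
lesion under all five (AT, RG, WT, GCM2–GCM6 — the cluster count is capped
at six for lesions under ~11.5 mL).  One replicate per phantom is the
default, matching a single physical scan; trend analyses in the test suite
and acceptance script use 10 (dichotomy) or 3 (battery) noise replicates
with seeds decorrelated across phantoms.  Runs are deterministic: the
metrics CSV reproduces byte-for-byte, and the JSON manifest records the
configuration and SHA-256 of every written file.

## What the synthetic data does and does not show

The generator reproduces the *geometry* of the physical technique
(ground-truth-paired heterogeneous, necrotic and irregular lesions at
clinical voxel sizes and blur) but not its full physics: no reconstruction
artefacts, no attenuation/scatter, no printer non-uniformity (printing is
emulated, then calibrated, but the simulator consumes the ideal template),
and a structureless background by default.  Passing tests therefore
demonstrate algorithmic correctness and the direction of the documented
effects, not clinical-grade accuracy figures.

One quantitative limit deserves emphasis: with a 6.4-mm-FWHM PSF, the
40 %-volume core of an 11 mL necrotic lesion (equivalent radius ~10 mm) is
almost entirely within blur reach of the hot shell — in the noiseless
image the 90th-percentile core intensity (2.66) exceeds the shell mean
(2.51).  Threshold- and gradient-based methods consequently include the
outer ~70 % of core voxels, and no intensity-driven method could exclude
more than ~90 % of the core at this geometry: the information is not in
the image.  The qualitative dichotomy survives — AT and WT leave a visible
central void while RG and GCM deliver filled masks — but "excludes the
core" is, at this resolution, a statement about the core's interior, not
about every core voxel.

## Numerical choices

Bisection tolerance 10⁻⁶ (calibration inversion); FCM convergence 10⁻⁶ of
the intensity span on cluster means, variance floor 10⁻¹² of the squared
span; empty FCM clusters trigger one quantile re-initialisation, then an
error.  AT oscillations (mask cycles) return the last mask with
`converged=False`.  Gaussian blurs use edge-replicating padding so constant
fields are preserved.  All ties (marker windows, seeds, argmax over
clusters) break to the lowest linear index.  Seeds derived inside the
pipeline stay below 2³¹.
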