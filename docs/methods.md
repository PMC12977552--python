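# Methods

## Scope

`retquant` packages the quantitative core of a retinal neurodegeneration
workflow: counting retinal ganglion cell (RGC) somas on RBPMS-stained
flat-mount images, summarizing the spatial organization of Iba1+ myeloid
cells, quantifying dot-blot cytokine membranes, and deriving the summary
arithmetic (percent reduction, fold change, percent-of-control) used to
compare groups. Because studies of this kind typically do not deposit raw
images, the package ships a first-class synthetic-data generator that
produces ground-truthed inputs for every stage; all quantitative claims
about the pipeline are made against that ground truth.

## Soma counting

### Model

An RBPMS-stained soma in a flat-mount composite appears as a bright,
approximately round blob of ~12 um diameter over a background contaminated
by uneven illumination and camera noise. The counting pipeline is a fixed
operator chain:

1. **Background suppression.** Subtract a constant absolute background
   (clamped at zero), apply a grayscale morphological opening with a small
   disc (removes sub-cellular speckle), then subtract a local background
   estimated by a grayscale opening with a disc much larger than a soma
   (a white-tophat; removes smooth illumination structure).
2. **Declumping.** Two rounds of (Gaussian blur, grayscale erosion with a
   small disc). Erosion deepens the intensity valley between touching
   somas; the blur keeps the erosion from amplifying pixel noise.
3. **Binarization.** Local adaptive threshold: a pixel is foreground when
   its intensity exceeds the block-local mean by more than a fixed offset.
   Adaptive rather than global thresholding is what makes the pipeline
   insensitive to residual illumination gradients.
4. **Center detection.** Euclidean distance transform (EDT) of the
   foreground; candidate centers are EDT local maxima, with plateau maxima
   (discs produce plateaus) collapsed to their centroids. Each candidate
   carries the pixel area of its supporting connected component.
5. **Filtering.** Candidates outside the per-object area bounds are
   discarded; the rest are visited in descending EDT value (ties: larger
   area, then row-major position) and any candidate closer than the
   minimum intra-center distance to an accepted one is suppressed. The
   accepted list is the cell coordinate table.

All subtractions clamp at zero, so images stay non-negative through the
chain. Masks (whole-retina outline or square ROIs) restrict the detection
list rather than the image, which keeps mask edges from creating artificial
gradients inside the filtering stages; a consequence is that a masked count
is always a subset of the unmasked count.

### Parameter derivation

Every length parameter is derived from the nominal soma diameter expressed
in pixels, d = diameter / (um/px); at the reference calibration of
0.5 um/px and a 12 um soma, d = 24. `CountingConfig.from_geometry` applies:

| parameter | rule | value at d = 24 | role |
| --- | --- | --- | --- |
| opening radius | d/8 | 3 px | speckle removal |
| background kernel radius | ~d | 25 px | local background scale |
| declump blur sigma | d/24 | 1 px | noise control |
| declump erosion radius | d/12 | 2 px | valley deepening (2 rounds) |
| adaptive block | ~2.1 d, odd | 51 px | local mean window |
| area floor | 0.25 pi (d/2 - d/6 - d/24)^2 | 38.5 px | sub-cellular reject |
| area ceiling | 4 pi (d/2)^2 | 1810 px | cluster/artifact reject |
| peak separation | d/3 | 8 px | EDT maxima spacing |
| intra-center distance | 5d/12 | 10 px | duplicate suppression |

Two of these deserve comment. The area floor is referenced to the *eroded*
soma footprint: the two declump rounds shave roughly
iterations x erosion + blur_sigma = d/6 + d/24 off a soma's mask radius,
so 25% of the shrunken footprint plays the role "a quarter of a nominal
soma" plays on the raw image. The intra-center
distance is deliberately smaller than the closest physical center spacing
of touching somas (0.8 diameters): detected centroids of touching pairs
jitter a few pixels toward each other, and a suppression radius at the
physical spacing silently deletes one member of such pairs. 5d/12 (half the
physical minimum plus margin) suppresses genuine duplicates — which the
EDT peak spacing of d/3 already bounds — without eating real neighbors.

The adaptive offset (400 intensity units by default) is the only parameter
expressed in intensity rather than geometry; it should sit well above the
residual noise after background suppression and at roughly 10-15% of a
typical soma peak amplitude. It is exposed in the config and in
`from_geometry` for images on other intensity scales.

### Validation

The accuracy claim is measured, not assumed: on 20 synthetic tiles at the
default realism parameters (~4,500 ground-truth cells), the mean absolute
count error of the default pipeline is in the 2-4 per 1,000 cells range
(`tests/test_acceptance.py`, `scripts/acceptance.py`). Error grows
monotonically with clump fraction and with noise once the peak
signal-to-noise ratio drops below ~3, and the counter is exact on isolated
noise-free somas.

## Synthetic flat-mounts

The generator emulates the imaging regime the counter assumes:

- **Geometry.** Cells are placed in a rectangular tile (or a disc when a
  retina outline is wanted) wholly inside the window (center at least one
  soma radius from the border). Non-clumped cells keep a minimum pairwise
  separation (default 0.9 soma diameters) via grid-accelerated dart
  throwing; an infeasible density raises an error naming the achievable
  maximum rather than silently under-packing.
- **Clumps.** A configurable fraction of cells is placed in touching
  clumps. Clump sizes follow a shifted Poisson (minimum 2); members chain
  off an existing member at a center spacing uniform in [0.8, 1.2] soma
  diameters and keep at least 0.8 diameters from every clump mate. These
  are the cases the declumping stage exists to solve.
- **Rendering.** Each soma is an additive isotropic Gaussian truncated at
  3 sigma with sigma = radius/2 — round, filled somas as a pan-RGC
  cytoplasmic stain produces. Radii and peak intensities are normal draws
  (clipped positive).
- **Background.** Constant offset plus a planar illumination ramp of
  configurable peak amplitude in a seed-dependent direction, additive
  Gaussian noise, optional Poisson shot noise.
- **Defaults.** 512 px tiles at 0.5 um/px; 3,400 cells/mm^2 (the order of
  magnitude of RGC density in mid-peripheral mouse retina, consistent with
  ~50,000 RGCs over a ~15 mm^2 retina); soma radius 6 +/- 0.5 um; peak
  3,000 +/- 400 over a 500-count offset with a 300-count ramp and 60-count
  noise on the 16-bit scale; 20% of cells clumped. One 512 px tile holds
  ~220 cells.

What the generator does *not* emulate: optical point-spread functions,
vignetting, vasculature and optic-nerve-head shadows, staining
heterogeneity across the retina, z-projection artifacts from curved
flat-mount petals, and debris. Passing the benchmark therefore demonstrates
correctness of the algorithmic chain under controlled conditions, not
field performance on arbitrary microscopes; the config is the instrument
for adapting to real images.

Sector loss (`apply_sector_loss`) models mosaic gene deletion: cells whose
polar angle about the window center falls in a sector are labeled
`cre_pos` and removed independently with the stated probability, cells
outside are labeled `cre_neg` and untouched. This yields scenes with known
in-sector survival for validating regional quantification.

## Myeloid-cell spatial statistics

Two readouts, matching how such data are measured in practice:

- **Density**: points per mm^2 in square ROIs (630 x 630 um^2 = 0.3969
  mm^2 in the study design), half-open membership so tiling ROIs never
  double-count.
- **Nearest-neighbor summary**: sample n reference cells (default 10)
  uniformly without replacement, average each one's k nearest-neighbor
  distances (default k = 5), then average the per-reference means into one
  value per region and replicate. Sampling is seeded and performed over a
  coordinate-sorted canonical order, so the summary is reproducible and
  independent of point-list ordering. When fewer than n points exist, all
  are used and the summary is flagged.

No edge correction is applied — distances are raw Euclidean distances in
the flat-mount plane, as an image-analysis tool measures them. Reference
cells near the window boundary therefore have upward-biased distances; the
window geometry travels with the summary so downstream users can assess
the bias. The test suite quantifies the unbiased regime: for simulated
homogeneous Poisson (CSR) patterns with references restricted to an inner
core, empirical mean k-NN distances match the closed form
E[d_k] = k C(2k,k) / (4^k sqrt(lambda)) within Monte-Carlo error, and
Thomas-clustered patterns at equal intensity give strictly smaller
summaries — the property that makes the statistic a clustering readout.

The point-process generator simulates CSR by a Poisson count and uniform
placement, and the Thomas process by Poisson parents in a window dilated by
4 sigma (so offspring of outside parents are not lost at the edges),
Poisson offspring counts, and isotropic Gaussian displacements clipped to
the window.

## Dot-blot densitometry and clustering

Quantification follows fixed-ROI film densitometry: circular ROIs of one
shared radius, integrated density (sum of pixel values over pixels whose
centers fall in the circle), one same-sized background ROI over blank
membrane subtracted from every spot (clamped at zero), technical duplicates
averaged *after* subtraction, and log10 transformation with a floor
(default: 1 integrated-density unit, mapping empty spots to 0) to keep the
matrix finite. Subtracting integrated density against integrated density is
equivalent to mean-gray subtraction scaled by the shared pixel count, which
is why a single background measurement suffices.

Analyte profiles (rows) are clustered with Euclidean distance and
unweighted average linkage (UPGMA) via `scipy.cluster.hierarchy`; an
O(n^3) re-agglomeration oracle in the test suite verifies topology and
merge heights exactly. Heatmap leaf order is canonicalized: at every merge
the subtree containing the lexicographically smallest analyte name goes
left, making the rendered row order deterministic and invariant to input
row order. Scans are assumed bright-signal-positive; dark-spot films are
inverted via the CLI `--invert` flag.

The membrane generator draws each analyte as two duplicate uniform discs of
amplitude proportional to abundance, Gaussian film blur, constant
background, optional noise. Blur preserves integrals, so background-
subtracted integrated density is exactly proportional to abundance in the
noise-free limit — the linearity the quantification relies on (verified at
R^2 > 0.999).

## Summary arithmetic

`percent_reduction` = (control - treated)/control x 100 and `fold_change`
= treated/control, both rounded half-away-from-zero at the printed
precision so derived figures are reproducible from their printed inputs;
the identity reduction/100 + fold = 1 holds exactly pre-rounding.
`percent_of_control` normalizes per-segment axon counts to a control group
mean. Group dispersion is reported as SEM with the n-1 sample standard
deviation. Inferential tests are out of scope: tables are built for
consumption by standard statistical software.

## Numerical conventions

- Coordinates: origin at the top-left pixel center, x rightward, y
  downward; microns = pixels x microns-per-pixel everywhere.
- Rectangles and ROIs are half-open; discs are closed.
- All generators draw from one `numpy` Generator seeded by the spec, so
  identical spec + seed reproduce outputs bit-exactly.
- Greedy suppression ties break by larger area, then row-major position —
  fully deterministic.
- Images are processed as float64 and quantized to 16-bit only on file
  output.

## Problem sizes used in the shipped checks

The counting benchmark uses 20 tiles of 512 px (~220 cells each, ~4,500
total); the CSR agreement check uses 200 patterns per intensity at
intensities 50, 200 and 800 points/mm^2; clustering oracles run on 5-row
matrices; these sizes give stable statistics while keeping the whole suite
fast on a single CPU.

## Known limitations

- The counter's accuracy bound is certified on synthetic scenes only (see
  above); real flat-mounts add artifacts the generator does not model.
- Counting assumes a single nominal soma scale; strongly size-heterogeneous
  populations would need per-population configs.
- Nearest-neighbor summaries carry window-edge bias by design (documented,
  not corrected).
- The membrane model has no grid distortion or saturation; automatic grid
  registration of real membranes is out of scope.
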