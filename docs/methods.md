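# Methods

This note documents the models, conventions and numerical choices behind
`otolithct`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic validation does and does not
demonstrate.

## Coordinate and HU conventions

All grids use axis order (slice, row, column) with 0-based indices; world
coordinates are voxel centers, `world = origin + index · spacing` (mm).
One stated convention, used by every module, prevents silent axis swaps.
HU values are clamped to [−1024, 3100] on read — air at the bottom, the
largest tabulated calcium-compound value (calcium oxide) at the top — so
transfer functions operate on a bounded range. NIfTI-1 is the canonical
interchange format and round-trips integer HU exactly; DICOM series are
read-only (HU = raw × slope + intercept, spacing from `PixelSpacing` and
slice positions, hard error on missing calibration or inconsistent
orientation, warning on non-CT modality). Gantry tilt, multi-frame DICOM
and non-axial acquisitions are out of scope.

## Material classification

The classifier ships the published CT-value table of calcium compounds in
the human body. Material masks use closed ranges (`low ≤ HU ≤ high`),
matching the printed ranges; comparisons are exact, with no epsilon, since
clinical HU grids are integral. Two quirks are preserved deliberately:

* the struvite row's published mean (1248) lies outside its published
  range (987–1187); the row is kept verbatim and constructing such a
  definition warns rather than fails;
* the skull row carries a range only, no mean/SD.

## Opacity transfer function

The trapezoid is parameterized by its four breakpoints (defaults 140, 400,
600, 850 HU) and a maximum opacity (default 1.0). The published
description fixes only the breakpoints, calling the sides an "upward" and
"downward" curve; both are implemented as straight linear ramps — the
standard trapezoid reading, and the only shape fully determined by the
four breakpoints. Opacity is exactly zero at and beyond both feet, so a
voxel is visible iff 140 < HU < 850.

## Rendering

Orthographic, axis-aligned rays take one sample per voxel crossed
(nearest-neighbor lookup); compositing is front-to-back,
`A ← A + (1 − A)·α`, equivalently `A = 1 − Π(1 − αᵢ)`, and the pixel gray
value is `brightness × A`. There is no lighting model: the published
display is black-and-white shading at constant 100% brightness, so gray is
driven purely by accumulated opacity. Occlusion behind an α = 1 sample is
exact (the transmittance factor is exactly zero), with no early-exit
threshold needed. Arbitrary view vectors resample the volume trilinearly
on a ray grid at the smallest voxel pitch; axis-aligned output pixels
inherit the in-plane spacing of the two non-view axes so distances on the
image remain metric.

A consequence of pure opacity compositing worth knowing: any ray that
eventually crosses plateau-HU bone saturates to white, however much gray
material sits in front. Exposing the maculae as gray therefore requires
cutting the shell away *along the view axis* (two complementary cuts
isolating a slab), not just in front — the package's front-cut scenes do
exactly that.

## Morphology

The hit-miss transform follows the standard definition: position x matches
iff every B₁ offset lands on foreground and every B₂ offset lands on
background (i.e. B₂ is eroded against the complement). Out-of-bounds
probes count as background — conservative at volume edges. Thickening is
`X ∪ HMT(X, B)` and can only add voxels; contour extraction is X minus its
erosion and can only remove them. Defaults: 26-connectivity for connected
components (thin slabs at 0.5 mm slice pitch fragment under
6-connectivity), 6-connectivity for the contour erosion, minimum region
size 5 voxels (suppresses single-voxel noise hits at the CaCO₃ HU spread
of 38.4), and a thickening bank of the 8 canonical in-plane border-growth
pairs (B₁ = one of the 8 in-plane neighbors, B₂ = the origin) applied in
sequence. All of these, including user-defined structuring elements as
offset lists, are configurable.

Seeds are defined as the lexicographically smallest voxel of each
component — deterministic and permutation-invariant, fixing what "a seed
pixel of each region" leaves open. The vestibule region of interest is an
optional mask input (manual on a workstation); segmentation runs on the
whole volume when absent.

## Measurement

Width and length of a macula are not defined relative to any anatomical
axis in the source material, so the package uses an orientation-free
definition: extents along the principal axes (eigenvectors of the centered
second-moment matrix of voxel centers, in world mm), reported sorted as
length ≥ width ≥ thickness. Volume is voxel count × voxel volume. Cohort
summaries use the sample SD (n − 1), which is what reproduces the pooled
reference rows.

Extents span voxel *centers* and therefore underestimate the true object
extent by up to one voxel per axis (≈ 0.18 mm in plane, 0.5 mm across
slices at the default geometry). A `compensate` toggle adds one voxel
diagonal per extent to quantify this bias; it is off by default to keep
the definition minimal. All phantom-recovery numbers in the tests and the
acceptance report use the raw definition.

## Welch comparison

Only group summaries exist on both sides of the validation (the historical
reports print means; per-subject measurements are unavailable), so the
test is Welch's t from summary statistics with Welch–Satterthwaite degrees
of freedom, two-sided p from the Student t distribution at the
*unrounded* real-valued df — rounding df visibly moves the borderline
utricle-length p-value at these sample sizes (n = 7 vs 5). p-values are
reported at two decimals in comparison output, full precision retained
internally. Degenerate zero-variance inputs are defined rather than
fatal: equal means → t = 0, p = 1; unequal means → p = 0 with a warning.

The built-in reference table reproduces the seven historical rows
verbatim. Recomputing the pooled row from those rows matches the published
pooled mean/SD at two decimals for utricle length (2.98/0.28), saccule
width (1.34/0.15) and saccule length (2.51/0.27), but *not* utricle width
(recomputed 2.26/0.25 vs published 2.28/0.24). The published values are
retained as the comparison inputs; the discrepancy is treated as a
transcription artifact of the source table. No multiple-testing correction
is applied, matching the original analysis.

## Phantom

The phantom models only the contrast the method depends on:

| compartment | HU (mean ± SD) | rationale |
|---|---|---|
| background | −1000 | air |
| bony shell | 625 ± 50 | inside the published 400–850 skull range |
| lumen fluid | 15 ± 10 | water-like; no published endolymph/perilymph HU exists, configurable |
| maculae | 189 ± 38.4 | published CaCO₃ distribution |

Geometry defaults: 32 × 72 × 72 voxels at 0.50 × 0.18 × 0.18 mm (the
published acquisition: 0.5 mm slices, 96 mm FOV / 512 matrix = 0.1875 mm
in plane), a spherical 5.5 mm shell with a 0.8 mm wall, an utricle-like
ellipsoid of in-plane extents 2.2 × 2.7 mm and a saccule-like one of
1.1 × 2.6 mm — the scale of the histological reference. A "peanut" blob
(union of two offset ellipsoids with shared semi-axes, closed-form volume
via the two-unit-sphere lens) is available to mimic the described
peanut-shaped utricular macula.

Slab thickness defaults to 1.2 mm, with blob centers on slice centers.
This is a deliberate discretization choice: with 0.5 mm slices a blob then
intersects three slice planes and the voxel-count volume lands within ~1%
of the analytic volume (midpoint-rule behaviour), whereas sub-millimetre
slabs alias badly — the measured thickness of a 0.8 mm slab can be 0 or
0.5 mm depending on sub-voxel placement. The source material prints no
macula thickness; 1.2 mm is this package's choice of a representable
slab. Note the saccule's nominal in-plane width (1.1 mm) is slightly below
this thickness, so in the sorted (length, width, thickness) convention the
truth "width" of the saccule is its 1.2 mm slab dimension.

Noise is independent per-voxel Gaussian HU per compartment, with an
optional global noise term and optional Gaussian smoothing (mm) to emulate
reconstruction blur. Identical config + seed reproduce the volume bit for
bit. What the phantom does **not** model: cochlea and semicircular-canal
geometry, beam hardening, detector noise correlation, reconstruction
kernels, partial-volume physics beyond smoothing, or inter-subject shape
variation beyond axis scaling. Passing the recovery tests therefore shows
the chain is self-consistent on idealized anatomy at clinical voxel sizes
— not that it segments real temporal bones.

## Pipeline

The pipeline runs volume → classify → segment → render → measure →
compare and writes labels (NIfTI), renders (16-bit PNG), measurements
(CSV), a comparison report (JSON) and a manifest (config, seed, version,
config hash) sufficient to reproduce the run byte for byte. In phantom
mode it simulates a cohort (default 5 subjects, matching the study size):
per-subject noise realisations plus per-blob semi-axis scale factors drawn
from N(1, 0.1). Without that anatomical jitter the cohort SD collapses to
the segmentation noise floor and the Welch comparison degenerates; 10% is
a round, realistic inter-subject variation, smaller than the relative SDs
of the in vivo study row (7–73%). Organ assignment is by in-plane width
(widest region = utricle), which separates cleanly at the default
geometry. Cohort p-values reflect the synthetic conditions — including the
center-to-center extent underestimate — and are a demonstration of the
plumbing, not a reproduction of the in vivo comparison; the in vivo
comparison itself is reproduced exactly from the published summary rows
(p = 0.54, 0.61, 0.79, 0.07).

Failures abort with the failing stage's name; outputs already written are
renamed with a `.partial` suffix.

## Problem sizes

The default phantom (≈ 166k voxels) and five-subject cohorts keep every
test and the acceptance script in the seconds range; the recovery
properties are resolution questions, not scale questions, and a second,
finer grid (0.25 × 0.09 × 0.09 mm) is used only to check convergence of
measured extents toward the analytic truth.

## Known limitations

* The texture-synthesis heritage of the display chain is reduced to the
  operators that are actually defined (HMT, thickening, contour work);
  no neighborhood-matching synthesis step is implemented.
* Perspective cameras, color transfer functions, gradient shading and
  interactive manipulation are out of scope.
* Measurements on rendered 2D views are not implemented; dimensions are
  measured in 3D, which is this package's definition of width/length.
* DICOM writing is unsupported (NIfTI is the interchange format).
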