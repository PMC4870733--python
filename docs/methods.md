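# Methods

`slicekin` quantifies rigid-body displacements between two solid bodies
from single-plane or biplanar MR-like slice images, without implanted
markers. The workflow has four stages: (1) calibrate the slice-imaging
volume from a bead grid, (2) model the solid bodies as 3-D solids, (3)
image them at a series of set displacements, (4) register the solid models
to each slice image ("rotoscoping") and read joint-coordinate-system
displacements off the registered poses. A test–retest reliability layer
analyses two sessions of such measurements. Because no public dataset of
this kind exists, a phantom simulator generates every input with ground
truth retained, so each stage can be validated offline.

## Phantom and signal model

The physical test objects are modelled directly:

* **Solid bodies** — two 40 mm cubes, each with an hourglass-shaped bore
  through its centre: a symmetric double frustum, 7 mm diameter at the
  faces tapering linearly to a waist at the centre. The waist diameter of
  the physical cubes is not a measured quantity; it defaults to 3 mm and
  is a parameter. The bore gives the silhouette a distinctive bow-tie
  cross-section that anchors the registration. The cube pair sits with a
  10 mm gap between adjacent faces, i.e. 50 mm between centres, which is
  also the centre of rotation used in the rotation trials.
* **Calibration grid** — four plates normal to the scanner bore (y) axis,
  30 mm apart, each carrying a 4×4 array of 2 mm beads at 20 mm pitch.
  Plates are modelled as 80 mm × 80 mm squares (consistent with the bead
  lattice plus margin). Three extra off-lattice beads on two adjacent
  plates define the grid axes; they are deliberately placed off the
  lattice diagonals so that every dihedral symmetry of the square bead
  array is broken and the bead labelling is unambiguous from a single
  plate image.

The imaging model is purely geometric: material occupancy is 1, air 0. A
pixel's noiseless value is the fraction of its slab column occupied by
material (the partial-volume effect), computed by stratified sub-sampling
(default 4 samples across the slab per pixel; more in accuracy-critical
tests). The image is then convolved with an in-plane Gaussian blur
(default FWHM 1 mm) and Gaussian noise is added (default SD 3 % of full
signal). No pulse-sequence contrast physics (T1/T2, TR/TE, coil
sensitivity, susceptibility) is modelled; the technique uses silhouette
morphology only, so the two sequences of interest are represented solely
by their resolution parameters: 0.78125 mm pixels / 5 mm slices
(T1-like), 0.98 mm pixels / 8 mm slices (fast-sequence-like).

Two consequences of this model worth noting. First, for a slab through
the bore axis the silhouette "hole" is not the idealised thin-slice
bow-tie: the slab integrates the circular bore over its thickness, so the
integrated material area of a 5 mm slab exceeds the polygonal value by
~2–3 %; the thin-slab limit recovers the polygon exactly and is what the
renderer's area test checks. Second, monotonicity under slab thickening
holds for integrated material (fraction × thickness), not for the
fraction itself, which dilutes when the slab extends past the solid.

**Trial design.** Trial series enumerate displacement levels 0–20 (5 mm or
5° steps) with the study's replicate counts (7 translation, 6 rotation, 4
biplanar per level), neutral frame first and frames ordered by level so
that consecutive frames never jump more than one increment — the
sequential registration initialises each frame at the previous solution
and needs bounded jumps. Each trial's true displacement is the nominal
level plus a uniform placement jitter (default ±0.2 mm / ±0.2°) emulating
manual caliper positioning of the cubes; the registration never sees the
truth. Biplanar frames carry two orthogonal slices: the mid-sagittal
(z–y) plane and an axial (z–x) plane, the latter keeping both cubes and
both in-plane translation components observable.

## Calibration

Bead centroids are detected by light pre-smoothing, an iterated Otsu
threshold (beads cover a tiny image fraction, so a single Otsu pass can
land inside the background noise; the threshold is re-estimated on the
suprathreshold pixels until it clears the background by 4 robust SDs),
connected components with a [25 %, 400 %] bead-disc area filter, and
intensity-weighted (subpixel) centroids. Correspondence tries the four
90° rotations and the reflection of the known bead pattern and keeps the
minimum-cost assignment (Hungarian algorithm); the axis beads make this
minimum unique, and plates without axis beads inherit the orientation
resolved on an axis-bead plate of the same rigid grid.

Each plate is fitted with an 8-parameter plane-to-image homography by
normalized DLT (Hartley normalization; stored coefficients scaled to
magnitude ≤ 1). A classical 11-parameter 3-D DLT is degenerate here
because each plate's control points are coplanar; the planar DLT plus the
known 30 mm plate spacing is the well-posed equivalent. Because MR slices
are tomographic rather than projective, the volume model is
affine-orthographic: a single 3-D affine correction from the scanner's
nominal sidecar geometry to the grid's world frame, fitted by least
squares over all plates' beads. In a perfect scanner this correction is
the identity; its residual (reported in mm) measures calibration quality,
and a residual above 1 mm marks the plate fits as mutually inconsistent.
The recovered pixel size is estimated independently of the sidecar from
the per-plate homography Jacobians against the bead world coordinates.

Pixel coordinates are 0-based pixel centres; world units are millimetres
throughout.

## Registration (automated rotoscoping)

The human operator of the original workflow is replaced by maximization
of the zero-normalized cross-correlation (NCC) between the observed slice
and a predicted silhouette template. The template uses the same
partial-volume operator as the simulator, but its pixel lattice is mapped
into world space through the calibrated volume mapping — with a perfect
calibration the template equals the simulator's noiseless image exactly,
which pins the shared-operator contract in tests.

Optimization is a Nelder-Mead simplex (derivative-free, like a human
nudging a model) over the degrees of freedom appropriate to the trial:
translation-z only, rotation-x only, z+x for biplanar (scores summed over
the two views), or full 6-DOF (off by default for single-plane data,
where out-of-plane motion is weakly observable). Defaults: 5 restarts,
the first from the initialization and the rest jittered ±2 mm / ±5°; an
explicit initial simplex of 2 mm / 4° steps (the scipy default simplex at
a zero start is microscopic and stalls); convergence tolerance 0.005 mm.
Rotation parameters are clamped to ±45° because the bored cube has 4-fold
symmetry with equivalent score basins every 90°; the trials stay ≤ 20°.
A frame whose best restart scores below 0.5 (an empirically safe margin —
correct registrations on simulated data score > 0.9) is recorded as a
failure and the series continues from the last success.

The neutral frame registers both bodies sequentially from the nominal
experimental placement; every later frame registers the moving body only,
initialized at the previous frame's solution. The joint axis frame (AJX)
is assigned at the neutral registration — axes aligned with the
calibrated world frame, origin midway between the bodies — and can be
saved and reloaded so a second session reuses the first session's axes.
A `poses_override` / `--poses-from-file` path bypasses optimization so
externally produced (e.g. manually registered) poses can be analysed with
the same extraction code.

## Displacement extraction

The relative pose of the moving body with respect to the stationary body
is formed in the stationary body's frame (making the result invariant to
a common world transform), differenced against the neutral relative pose,
and expressed in the joint axes: translations are projections of the
relative-translation change onto the axes; rotations use an intrinsic
x-y-z Euler decomposition. The trials only ever rotate about one axis, so
any convention agreeing on single-axis rotations would do; this one is
fixed for reproducibility, and configurations within 10° of gimbal lock
are flagged rather than silently decomposed. Values are signed
(+z = increasing scale reading, right-hand rule about +x); magnitudes are
taken only in the reliability layer.

## Reliability statistics

* **CV** per trial: sample SD of the two session values over their mean,
  ×100. For a pair this is |x₁−x₂|/√2 ÷ mean — the n−1 convention, the
  one that reproduces the worked 4.44 % for (11.5, 10.8). Zero-mean pairs
  (possible at the 0-displacement level) are undefined, flagged and
  skipped with a count. Per-level "mean CV" averages per-trial CVs
  (computing a CV from session means instead would collapse the replicate
  variation and is not what per-level rows of a trial table show).
* **ICC(2,1)**: Shrout–Fleiss two-way random-effects single-measure form
  from ANOVA mean squares — chosen because systematic between-session
  bias counts against agreement. The 95 % CI is the McGraw & Wong F-based
  interval (cross-checked against `pingouin` in tests).
* **Bland–Altman**: differences session1 − session2 (sign reported), bias
  ± 1.96·SD limits; heteroscedasticity classified by the R² of OLS of
  |differences| on pair means, threshold 0.1.
* **Ratio LOA**: [(SDdiffs/AVGmeans) × 1.96] × 100, with the systematic
  bias (mean difference) reported separately from this random-error
  component.
* **t-tests**: paired between sessions, independent between sequences
  (delegated to scipy, verified against the textbook formula in tests).

The simulated rater (`SessionPairSim`) draws measurement =
truth + bias + N(0, σ²) independently per session and trial, so the
statistics can be exercised with known variance components: the expected
ICC is s_t²/(s_t² + σ_e²) with s_t² the (n−1) variance of the true
values.

## Problem sizes and numerical choices

Default test and acceptance runs use the full study designs (35
translation, 30 rotation, 20 biplanar frames; both imaging presets),
256×256 images, 4 slab sub-samples per pixel for registration and more
(up to 3×3×8) where geometric accuracy is asserted; Monte-Carlo checks
use 100 seeds (plate-fit residual band, ICC oracle), 200 replicates (ICC
parameter recovery) and n = 10⁵ (Bland–Altman coverage). All randomness
flows from explicit integer seeds; identical configurations produce
byte-identical outputs, including images.

## What the simulations do and do not show

Passing tests demonstrate that the geometry chain (calibration →
registration → extraction) is internally consistent and recovers known
displacements to a fraction of a voxel under the stated noise model. They
do not validate against real scanner physics: gradient nonlinearity,
susceptibility distortion, sequence-dependent contrast, through-plane
blur anisotropy and human-rater behaviour are all outside the signal
model. In particular, the NCC optimizer is a documented stand-in for the
human operator; no claim is made that its error distribution matches a
human's, and published human test–retest tables cannot be reproduced here
because the underlying per-trial data are not public. Accuracy against an
independent gold standard (rather than test–retest reliability) would
require a physical study and is out of scope.
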