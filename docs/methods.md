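# Methods

## Problem and approach

The prostatic urethra cannot be seen on planning CT; delineating it
normally requires an invasive urethral catheter. Because radiation dose to
the urethra correlates with late urinary toxicity, an automatic estimate
of its position from structures that *are* routinely contoured — the
bladder and the prostate — is clinically useful for EBRT planning.

`uroseg` implements a contour-only localization pipeline:

1. **Encoding.** Organ masks (from DICOM RT Structure Sets or NIfTI) are
   resampled to 1 mm isotropic voxels (cubic spline on the binary field,
   threshold 0.5), combined into a 256-level grayscale input volume
   (bladder 64, prostate 128, background 0; prostate wins on overlap) and
   a target volume (urethra 255). A 128³ window is cut around the
   prostate: in-plane centered on its centroid, with the apex 10 voxels
   above the inferior edge. For the 2D variant the window is collapsed by
   maximum intensity along Y (coronal) and X (sagittal) and upsampled ×2
   to 256×256 at 0.5 mm/px (cubic for inputs, nearest for targets).
2. **Segmentation.** A residual U-Net predicts the urethra from the
   encoded input — either one 3D model on the 128³ volume, or a pair of
   2D models (coronal + sagittal, always trained and applied as a unit).
   Backends are pluggable behind one `predict` contract; a geometric
   oracle backend renders the phantom's analytic centerline as a 5 mm
   tube, so reconstruction and evaluation can be tested with zero model
   error.
3. **Reconstruction.** Raw predictions may be irregular, so on every 1 mm
   X–Y plane containing prostate a single coordinate is extracted: the X
   centroid from the coronal prediction and the Y centroid from the
   sagittal prediction (2D), or the in-plane centroid of the predicted
   voxels (3D). Planes with no prediction are filled by linear
   interpolation in z inside the predicted extent and nearest-value
   extrapolation at the ends. A disc of 5 mm diameter is drawn around
   each coordinate (voxel-center distance ≤ radius, boundary inclusive);
   the disc stack is resampled back to the original CT grid (cubic
   spline, threshold 0.5).
4. **Evaluation.** Centerlines are per-slice in-plane centroids of a
   mask. CLD is the mean over shared slices of the 2D Euclidean distance
   between predicted and ground-truth midpoints; PWR(r) is the percentage
   of shared slices with distance ≤ r (3.5 and 5 mm by default). CLD is
   also reported for the superior/middle/inferior thirds of the
   prostate's craniocaudal extent.

## Coordinate conventions

X = left–right, Y = anterior–posterior, Z = slice axis, with the Z index
increasing inferiorly (so "prostate at the bottom" is large z). Arrays
are indexed `[x, y, z]`; world position of a voxel is
`origin + index × spacing` (voxel-center convention). Only axis-aligned
grids are supported; oblique acquisitions are rejected at read time.

## Reference training conditions

The full-size model configurations are kept as defaults of
`ModelConfig.default_2d()` / `default_3d()`:

| | 2D | 3D |
|---|---|---|
| residual units | 3 | 4 |
| channels | 16, 32, 64, 128, 256 | 32, 64, 128, 256, 512 |
| strides | 2 | 2 |
| dropout | 0.5 | 0 |
| batch size | 4 | 2 |
| epochs | 1200 | 1000 |

Both use DiceCE loss (equal weighting of soft Dice and BCE), Adam at
learning rate 1e-4, a random 70/10/20 train/validation/test split shared
between variants, early stopping with the checkpoint of lowest validation
loss, and label-synchronized augmentations (random scaling ±10%, rotation
±10°, translation ±10 voxels, random crop, elastic deformation σ=5 /
magnitude 2 voxels — the magnitudes are our choices; only the kinds are
prescribed). Fivefold cross-validation over the training cases is
available for choosing between candidate configurations (lowest mean
held-fold DiceCE; ties keep list order).

The network itself is a self-contained numpy implementation (`_nn.py`):
stride-2 residual encoder, nearest-upsample + conv decoder with skip
concatenation, instance normalization, sigmoid head binarized at 0.5.
Backpropagation is hand-written and verified against finite differences
in the test suite. The final 1×1 convolution's bias is initialized to −4
(the approximate background log-odds, foreground being ~1% of pixels),
which removes the long initial phase of learning to suppress background.
Everything is float32 and deterministic for a fixed seed.

## Synthetic phantom

Clinical contour data with catheter-defined urethra ground truth are not
publicly available, so the package ships a generator of synthetic pelvic
anatomies with *analytically known* centerlines:

* prostate: ellipsoid, volume log-normal with mean 35.67 mL, SD 14.21 mL,
  truncated to 14.59–100.60 mL; axis ratios ~N(1, 0.1) clipped to
  [0.75, 1.25];
* bladder: ellipsoid superior to the prostate, abutting or slightly
  overlapping at the bladder neck (offset U(−4, 0) mm); bladder size is
  treated as an independent nuisance parameter (filling state is not
  modeled);
* urethra: smooth parametric path from the bladder neck to the prostate
  apex. The left–right tilt (the known hard case, concentrated in the
  upper prostate) is an X-offset weighted by a smoothstep that decays to
  zero over the superior third; an anterior bow in Y is a symmetric
  parabola scaled by a dimensionless curvature. Both offsets are clamped
  to stay inside the local prostate cross-section. The ground-truth mask
  is a 5 mm tube around the path. By default 10% of sampled cases carry
  a strong (≥15°) tilt, the rest mild tilt U(−10°, 10°);
* grids: in-plane 0.8/1.0/1.2 mm, slices 2.0/2.5 mm, covering ≈96 mm
  laterally and ≈144 mm craniocaudally (default explicit grid: 96×96×72
  at 1×1×2 mm).

What the phantom does **not** emulate: CT intensities (the pipeline never
reads them), inter-observer contouring variability, non-ellipsoidal organ
shapes, catheter-induced urethral deformation, rectum and other OARs.
Passing tests therefore demonstrate the correctness of the pipeline's
geometry, metrics and learning plumbing — not clinical accuracy on real
anatomy.

## Numerical choices

* Binary fields are interpolated with cubic splines and thresholded at
  0.5; values exactly 0.5 count as inside.
* Polygon rasterization uses the even-odd rule with voxel centers exactly
  on an edge counted inside (deterministic tie-break).
* Disc membership: center distance ≤ radius, boundary inclusive — on a
  center-aligned 1 mm grid a 5 mm disc contains exactly 21 voxels.
* The ×2 projection upsampling maps pixel `u` to window coordinate
  `0.5·u` mm; the 2× grid convention introduces a fixed ≤0.25 mm bias
  that is far below the evaluation tolerances and identical between
  prediction and target spaces.
* 2D coordinate extraction pools the two 0.5 mm image rows overlapping
  each 1 mm slice and takes the binarized-pixel centroid (equal weights).
* Prostate thirds are defined on the craniocaudal *world extent* (not
  slice counts), each slice assigned by its center; slices where either
  centerline is absent are excluded from both numerator and denominator
  of CLD and PWR.
* Degenerate inputs raise typed errors (`EmptyPredictionError`,
  `AnatomyError`, `GeometryError`, ...) rather than propagating NaNs; a
  wholly empty prediction is an error, an empty *plane* is filled by the
  interpolation policy.

## Problem sizes used in tests and the acceptance script

The learning demonstration trains the reduced configuration
(`ModelConfig.tiny_2d`: 1 residual unit, channels 8/16/32, no dropout,
no augmentation, batch 4, Adam 1e-4, DiceCE) for up to 15 epochs with
early stopping (patience 10) on 60 phantoms, validates on 8 and tests on
20 — sizes chosen so the whole loop runs in minutes on one CPU while
staying well below the 3 mm pass level used in the test suite (the
acceptance script measures the actual mean, ≈2 mm, with PWR(5 mm) ≈
94%; the residual error concentrates in the strongly tilted minority of
cases, mirroring the known clinical failure mode). Oracle-backend
consistency runs use 20-case populations; metric equivalence uses 1000
random centerline pairs.

## Known limitations

* The from-scratch numpy U-Net trains orders of magnitude slower than a
  GPU framework; the reference 1200/1000-epoch configurations are
  supported in code but not exercised at full scale.
* `read_structure_set` implements a minimal RTSTRUCT dialect (closed
  planar contours, no referenced image series); contours between slice
  planes are rejected rather than interpolated.
* The 2D row→slice mapping averages the two overlapping 0.5 mm rows;
  whether the original workflow averaged or picked one is unspecified.
* Holes in contours are handled by even-odd parity only (no explicit
  XOR/keyhole semantics).
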