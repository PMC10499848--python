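# Methods

## Scope and model

`scapseg` covers the full path from a volumetric shoulder MRI to clinical
glenoid measurements: preprocessing, augmentation, 2D/3D V-Net
segmentation trained with a negative-log-dice objective, DSC-gated
ensembling, landmark-based morphometry, and the statistical protocol used
to compare model variants. Real patient scans are not distributed with the
package; every quantitative claim made by the test suite is therefore made
on synthetic phantoms with analytically known geometry (see below), which
validates the *mechanics and geometry* of the pipeline, not its accuracy
on clinical images.

## Preprocessing

A 512×512×248 acquisition (0.375×0.375 mm in-plane, 0.5 mm slice spacing)
is cropped by removing the first 112 rows and columns — the literal
reading of "first": indices 0–111 on both in-plane axes — and split into
two interleaved half-volumes (even slices / odd slices, slice spacing
doubled), giving two 400×400×124 volumes per scan. For odd slice counts
the halves differ by one slice (floor/ceil); the merge operation is the
exact inverse.

Three intensity-normalization schemes are provided. Training divides by a
single value drawn uniformly from `[max − j, max + j]` with `j` = 1000
(3D) or 500 (2D) intensity units; the distributional form is not dictated
by anything beyond "a random value within the range", so the uniform draw
is the minimal assumption and the half-width is configurable. A
non-positive draw is redrawn up to 10 times and then rejected — the
divisor must be strictly positive. Validation divides by the maximum and
then by the 85th percentile of the already-divided values; the percentile
is computed over **all** voxels with linear interpolation, which makes the
scheme scale-invariant and well defined. The jitter emulates
multiplicative coil-gain variation: a model trained this way tolerates the
residual scale difference between the training and validation schemes.

## Augmentation

Each augmented copy applies four independent transform families, each with
probability 0.30 *per family* (the plausible alternative — 30% per copy
overall — is a documented interpretation choice): random affine (rotation
±15°, isotropic scale 0.9–1.1, translation ±10 voxels), elastic
deformation (displacement ≤ 4 voxels, smoothness 8 voxels), Gaussian blur
(σ 0.5–1.5 voxels) and additive Gaussian noise (1–5% of the image
maximum). Magnitudes are package defaults chosen to deform without
destroying the thin scapular blade; all are configurable. Spatial
transforms use one parameter draw for image and mask; masks are resampled
nearest-neighbour and stay strictly binary. Datasets are expanded to the
originals plus eight copies per original ("augmented eight times" read as
eight additional copies, since the purpose is to increase the dataset).

## Network

The reference configurations are:

| field               | 2D     | 3D           |
|---------------------|--------|--------------|
| base channels       | 16     | 12           |
| levels              | 2      | 4            |
| convolutions/level  | [4, 4] | [1, 3, 4, 3] |
| bottom convolutions | 2      | 4            |
| learning rate       | 5e-4   | 1e-5         |

Per-level convolution counts apply to the encoder and are mirrored in the
decoder; downsampling is by strided convolution with channel doubling;
upsampling by zero-stuffed transposed convolution with channel halving and
skip concatenation; a residual add is used inside every block whose input
and output channel counts match. Kernels are 5 voxels (3 for the tiny
sanity configurations), activations are leaky rectifiers (slope 0.1), the
output is a sigmoid foreground probability, and elementwise dropout with
keep probability 0.95 runs at the end of each block during training only.
No normalization layers are used.

Convolutions are evaluated spectrally: the kernel is embedded (centred,
wrapped) in the field grid and multiplied with the input in the real-FFT
basis. This gives exact adjoints for backpropagation (verified against
finite differences to ~1e-6 relative error) at a cost independent of
kernel size. Boundary handling is therefore circular; inference
reflect-pads inputs to the next multiple of `2^levels` and crops the
output, which keeps wrap-around at the pad rim. Weights are He-initialized
from a seeded generator; everything is float32 (float64 available for
gradient checking).

## Training, validation, ensembling

Training minimizes `F = −log₁₀((2Σp·y + s)/(Σp + Σy + s))` with smoothing
`s = 1e-5` (only role: keeping the logarithm finite at near-zero overlap)
using Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), batch size 1 — one iteration is one
volume (3D) or one slice (2D); training examples cycle deterministically
and are re-normalized with a fresh random divisor every iteration. A
validation epoch runs every 90 steps (default): mean DSC over the
validation volumes with predictions binarized at 0.5 (whether the
monitored dice was soft or hard is an open choice; binarized matches how
the ensemble gate is consumed). "Improvement" means the best DSC increases
by more than 1e-4 — with strict float comparison, noise keeps patience
from ever triggering. The best checkpoint is restored at the end. Training
stops at 100,000 iterations or after 30 non-improving validation epochs.

Subjects are split into k = 5 consecutive folds without shuffling; sizes
differ by at most one, larger folds first. Ensembling admits every model
with validation DSC **strictly above** 0.70 (literal "above") and fuses
members by unweighted voxel-wise probability averaging (majority vote
available as an option); nothing specifies how heterogeneous members are
weighted, and the unweighted mean is the minimal symmetric rule. 2D
members are reconstructed to the full grid slice-wise along their own view
axis (axial = slice axis, coronal = row axis, sagittal = column axis); 3D
members predict the two interleaved halves, which are re-interleaved.

## Morphometry

All geometry is computed in physical millimetre coordinates
(`index × spacing`), so anisotropic voxels do not bias angles. Landmark
detection is a deterministic procedure of this package's own design (the
measurement *definitions* are standard clinical ones; how landmarks were
obtained on the original bone models is not specified and was likely
manual):

1. largest 26-connected component; surface voxels by erosion; outward
   normals from the gradient of a Gaussian-smoothed (σ 1.5 voxels) mask;
2. global principal axes: the first axis is medial–lateral (the blade
   dominates). Its lateral orientation is fixed by where the articular
   face is found: the largest connected surface patch whose normals lie
   within 40° of ±axis. The patch must be planar (r.m.s. thickness ≤ 2
   voxels) — a sphere has no such patch and is rejected;
3. the face patch is extended geodesically along the surface, gated by
   distance to the fitted plane (≤ 1.5 mean voxels), to recover the rim
   ring where smoothed normals bend away;
4. the superior axis is oriented by the asymmetric superior mass lateral
   to the blade (spine end, acromion); the anterior axis by the acromion's
   posterior position — a mirror-symmetric rule, so left and right
   scapulae yield identical signed measurements with no explicit side
   normalization;
5. glenoid rim points are the endpoints of the patch's in-plane principal
   axes (assigned superior–inferior vs anterior–posterior by alignment
   with the projected global axes, not by variance order, so
   wider-than-tall glenoids are handled); extents are padded by half a
   mean voxel per side because surface-voxel centres sit inside the
   continuous boundary. Using fitted axis endpoints instead of raw
   extremal voxels keeps rim-line *directions* stable to well under a
   degree;
6. the medial border point is the surface point farthest medially;
7. the fossa floor line is fit to per-bin (2 mm) topmost surface points in
   a window between the medial border and 9 mm medial of the glenoid
   centre; the fit is seeded on the medial 60% of bins and reclassified
   twice with a 2 mm residual gate, so lower neighbouring structures
   cannot tilt it; the lateral fossa point is the most lateral window
   point within 1.5 mm of the fitted line (limited to the line's inlier
   support);
8. the lateral acromion is the centroid of the most lateral 0.5 mm surface
   band (a band centroid, not a single voxel, for sub-voxel stability).

Measurement conventions: retroversion = 90° minus the angle between the
anterior→posterior rim vector and the centre→medial-border vector, signed
so retroversion is positive; inclination is the **raw** angle between the
inferior→superior glenoid line and the medially oriented fossa-floor line
(values straddle 90°, matching how clinical series report it; parallel
lines read 0°/180°); CSA is the angle at the inferior glenoid between the
superior-glenoid and lateral-acromion directions; the RSA angle is the
complement of the line angle between the inferior-glenoid→lateral-fossa
line and the fossa tangent. Surface distance maps are directed (each
surface voxel of A to the nearest surface voxel of B, via a Euclidean
distance transform with physical sampling). Mean differences between two
modalities' trial lists are `|mean(A) − mean(B)|`, reported rounded half
away from zero to two decimals (with an epsilon guard against binary
representation of exact halves).

## Statistics

Paired comparisons are gated by Shapiro–Wilk on the paired differences at
α = 0.05 (the normality assumption of the paired *t*-test concerns the
differences, not the two samples): *t*-test if normality stands, otherwise
a two-sided Wilcoxon signed-rank with exact null for n ≤ 25 and zero
differences dropped (the zero/tie policy changes small-sample p-values,
hence fixed and documented). Constant non-zero differences, where
Shapiro–Wilk is undefined, route to the rank test. Identical samples yield
a flagged degenerate result. One-way ANOVA uses the standard decomposition
and flags undefined F (all groups constant and identical). Significance is
p < 0.05, two-sided, with no multiple-testing correction. The exact
Wilcoxon branch is verified against a brute-force enumeration of all 2ⁿ
sign assignments, and the full gated procedure's type-I error under a
Gaussian null is calibrated at 5% ± 1.5% over 2000 replicates.

## Synthetic phantoms

The generator voxelizes a union of primitives in a canonical frame
(x lateral, y anterior, z superior): an elliptical glenoid disc (semi-axes
height/2, width/2; thickness 5 mm) rotated by the version angle about the
superior axis and the inclination angle about the anterior–posterior axis;
a connecting neck; a 3 mm blade extending 58 mm medially with a slanted
border that makes the most medial point unique; a spine ridge whose sharp
triangular crest *is* the fossa floor line; an acromion sphere; and a
connecting rod routed 7 mm below the crest so it cannot masquerade as the
fossa floor. The lateral fossa point and the acromion landmark are placed
in closed form from the requested RSA and critical-shoulder angles, so
those truths are exact; truth measurements are computed from the exact
continuous landmarks with the same formulas the measurement code uses,
making truth self-consistent to machine precision. (Version/inclination
couple weakly through the rotation composition, so the landmark-derived
retroversion differs from the construction parameter by ≲ 1° at the range
extremes; truth is always the landmark-derived value.)

Rendering assigns dark cortical bone (0.30), bright soft tissue (1.0,
everything within 25 mm of bone) and near-zero background (0.05), scaled
to ≈ 2000 arbitrary units, with a smooth multiplicative bias field and
additive Gaussian noise. The thick tissue region matters: as in a real
shoulder scan most of the field of view is tissue, so the validation
scheme's 85th-percentile division lands in the tissue band and the
train/validation intensity scales agree to within the training jitter. The
default cohort (heights 30–50 mm, widths 22–34 mm, version −15…+5°,
inclination ±15°, CSA 28–36°, RSA 22–32°, both sides) is generated at
0.5 mm isotropic resolution on a 200×96×176 grid; the pipeline default
uses 1 mm voxels on 104×64×96 to keep desk-scale runtimes.

What the phantoms do **not** emulate: real bone-marrow texture, cortical
thickness variation, pathology (bone loss, osteophytes, fractures), the
humeral head and surrounding anatomy, partial-volume physics, or MRI
artifacts beyond smooth gain and white noise. Passing recovery tests
demonstrates that the measurement geometry and the learning mechanics are
correct — not that the network segments clinical MRI at any particular
DSC.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at sizes chosen
for a single CPU core: morphometry recovery uses a 20-phantom grid at
0.5 mm (mean absolute errors ≲ 0.5 mm / ≲ 1°, against a 2 mm / 2°
tolerance); the training sanity run overfits one 64³ phantom with a
two-channel, two-level 3D network (≈ 22 k parameters) to validation DSC
> 0.9 within 500 iterations; the end-to-end pipeline trains two 200-
iteration fold models on six 1 mm phantoms and reaches fold DSCs ≈ 0.87–
0.89 and an ensemble DSC ≈ 0.90. Reference-size networks (Table above)
are constructed and run forward in the tests but not trained to
convergence.

Other fixed choices: binarization threshold 0.5 with an inclusive (≥) tie
rule, making thresholding monotone; dice 0/0 convention = 1 (two empty
masks agree); NIfTI for all volumes (masks uint8, probabilities float32),
spacing from the header, singleton dimensions squeezed, non-finite voxels
rejected at load; checkpoints are single `.npz` files with the embedded
configuration; all randomness flows through seeded numpy generators, and
pipeline stages derive namespaced seeds so each stage is independently
reproducible.

## Known limitations

- Circular (spectral) convolution boundary handling differs from the
  zero-padded convolutions of mainstream implementations; with
  reflect-padding at inference the difference is confined to the pad rim.
- The landmark detector assumes a scapula-like topology (dominant
  medial–lateral axis, planar lateral articular face, superior ridge). On
  degenerate inputs it raises a diagnostic error rather than guessing; the
  pipeline records such cases as missing measurements and continues.
- Fossa-window constants (4 mm medial offset, −9 mm lateral limit, 2 mm
  bins) are anatomical millimetre constants; measurements scale linearly
  with spacing only up to the discretization of the procedure.
- The statistical module implements the comparison protocol only for the
  designs used here (paired two-sample, one-way layout).
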