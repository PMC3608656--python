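# Methods

This note records the model underlying `scanwarp`, the choices made where
the design was genuinely open, and what the synthetic tests do and do not
demonstrate about real micrographs.

## Coordinate and data conventions

All modules share continuous image coordinates: x increases rightward
along columns, y downward along rows, origin at the center of pixel
(0, 0).  Images are single-channel float arrays (8/16-bit TIFF in, 32-bit
float maps out).  CSV outputs are comma-separated with a header row and
6-decimal fixed formatting; JSON outputs carry full double precision and
a provenance record (command, parameters, seed, version) but no
timestamps, so identical runs are bit-identical.

## Detection

The match kernel is a user-selected crop containing one pattern unit;
selection is deliberately manual (the paperwork of choosing a clean unit
does not automate well), with a highest-variance-tile convenience that is
never the default.  Normalized cross-correlation is computed as the
Pearson coefficient between the kernel and every fully contained image
window, via FFT convolutions of the image, its square, and the de-meaned
kernel.  The image's global mean is subtracted first; this leaves every
score unchanged but avoids catastrophic cancellation in the running-sum
variance.  Windows whose variance is numerically zero score 0, and values
are clipped to [−1, 1].  A test asserts equivalence with a double-loop
Pearson oracle to 1e−9 on small images and with an independent
established implementation to 1e−7.

Peaks: the energy map is thresholded (default 0.6 — the appropriate value
is pattern-dependent and the CLI exposes it), 8-connected components are
labelled, and each component yields one peak at its correlation maximum,
refined by the stationary point of a quadratic fit to the 3×3
neighborhood (clamped to ±0.5 px; a saddle falls back to the integer
maximum).  Components touching the border of the valid correlation region
are dropped; peaks closer than 2 px are merged keeping the higher score.
No shape filtering is applied — spurious detections are the RANSAC
stage's job to reject.  The subpixel refinement can be disabled to get
integer-pixel behavior.

## Lattice fitting

Triplets: for each peak the nearest neighbor defines g_right; candidate
third points are generated by rotating g_right about the peak by each
expected inter-basis angle (+60°/−120° for the hexagonal chip, ±90° for a
square grating), and the detection nearest the better candidate completes
the triplet if it lies within 15° of an expected angle and within 1.5×
the nearest-neighbor distance.  Offsets are sign-corrected into the
half-planes defined by the first triplet.

RANSAC (default 200 iterations, seeded; inlier tolerance 20 % of the
median nearest-neighbor distance): each iteration promotes one triplet's
offset pair to a model.  For a peak x_j and each basis direction, the
uncertainty is the distance from the nearest *other* detection to the
expected neighbor positions x_j ± g; a peak joins the consensus when both
directions are supported within tolerance.  Two details matter in
practice and were adopted after analyzing failure modes at high outlier
fractions:

* support must be conjunctive across the two axes — a model with one
  correct and one junk vector would otherwise certify every true peak
  through its good axis and win ties;
* the peak itself must not count as its own neighbor — otherwise any
  offset vector shorter than the tolerance certifies all peaks at once.

The winning model's basis is the mean offset pair over consensus triplets
that match it (directly or with axes swapped) within tolerance.  On an
equal-pitch 60° lattice there are six nearest neighbors, so any 60° pair
from {±a, ±b, ±(a−b)} is a legitimate basis of the same lattice;
restricting the average to model-matching triplets keeps the three axes
from being mixed.  Reported bases are canonicalized (each vector flipped
to non-negative x, the larger-x vector named g_r) for determinism.

## Indexing and refinement

Breadth-first traversal from an anchor — the consensus peak nearest the
consensus centroid that actually has lattice neighbors (a spurious
consensus member can sit near the centroid) — assigns integer
coordinates by ±1 steps toward detections within tolerance of x ± g_r,
x ± g_l.  Conflicting assignments exclude the peak (conflicts indicate
detection error, and the distortion fit is overdetermined); unreachable
peaks are excluded and reported.  Any anchor choice only shifts all
coordinates by a constant.

A closing refit then regresses the measured positions on the integer
coordinates, `x_i ≈ µ + c_r,i g_r + c_l,i g_l`.  This is the standard
consensus-then-refit closing step: it pools every indexed peak into the
generator estimate (the consensus mean carries sampling noise and local
warp gradients) and makes the expected locations {y_i} the least-squares
best regular lattice in the image frame — the reference the distortion
statistics are quoted against.  Without it the reported rms inherits a
percent-level scale error from whatever share of the affine the RANSAC
basis absorbed.

## Distortion model

The true shear/stretch of the target is unknowable and registration is
invariant to affine error, so a 6-parameter least-squares affine A maps
{y_i} onto {x_i} first.  The nonlinear model T: y′_i → x_i is fitted as
identity-plus-residual, the residual being two bivariate polynomials
(default degree 3, CLI range 1–7 with a warning when the coefficient
count exceeds half the correspondences) over coordinates normalized to
[−1, 1] across the field for conditioning.  The polynomial basis is the
full monomial set {x^j y^k : j+k ≤ degree}.

Displacement statistics evaluate d(p) = linA⁻¹(T(A p) − A p) on a grid
fixed in the expected-lattice frame, centered on the centroid of {y_i}.
Two properties motivated this exact form:

* composing any extra affine onto the measured points leaves the
  statistics unchanged (to ~1e−12 in practice): both the affine and the
  polynomial least-squares solutions compose exactly with the extra
  affine because all output components share one design matrix;
* after the refinement step A is the identity, so the statistic reduces
  to the plain image-pixel displacement |T(p) − p| — the distance from
  each transformed field location to its original position after affine
  alignment.

The grid uses midpoint (cell-centered) sampling at the requested pitch
(default 16 px), so every sample represents an equal share of the field
area and the coarse estimate agrees with a per-pixel evaluation to well
under 0.1 % on realistically sized fields (it reduces to pixel centers at
stride 1).  The rms is also reported as a percentage of the *field width*
(not the diagonal), which is the convention that reproduces both printed
percent figures from their printed rms values.  Statistics trim nothing;
the max is the true grid maximum.

Cropped fields re-fit the affine within the crop by default, so a crop is
evaluated as a small field imaged in its own right; evaluating the
full-field model inside the crop without re-fitting is available behind a
flag.  Percent values inside a crop divide by the crop width.

## Synthetic data

The generator emulates the calibration targets: unit centers on an ideal
two-vector lattice (60° hexagonal by default, 90° for the grating),
pushed through a known affine plus degree-3 polynomial warp, rendered as
filled squares whose boundary pixels carry exact area-weighted coverage
(anti-aliasing preserves subpixel position), with optional additive
Gaussian noise under a fixed seed.  Study fixtures use a 30×30 lattice
spanning a 4,000-px field; injected warps draw their affine-free rms from
2.5–35 px (noiseless recovery conditions) or 2–8 px with 0.3 px detection
jitter and 10 % uniformly scattered spurious points (robustness
conditions).  The warp's affine part is a mild centered rotation
(±0.5°), scale/shear (±0.5 %) and small translation; polynomial
coefficients are drawn at random and rescaled in two passes to the target
affine-free rms.

Ground truth is defined exactly as the measurement is defined: with Â the
least-squares affine over the true (ideal → warped) correspondences, the
true displacement at image-frame grid point p is |warp(Â⁻¹ p) − p|,
midpoint-sampled over a box centered on the warped-point centroid.  Under
a nonlinear warp there is no unique "true basis"; the well-defined
analogue, and the estimand of the refined basis, is the generator pair of
the best-fit regular lattice (the linear part of Â applied to the ideal
generators).

What passing these tests does *not* show: the renderer models neither
electron-optical physics nor realistic detector noise (only additive
Gaussian), nor tilted-specimen projection, target wrinkles, charging, or
contamination; thresholds that work on clean synthetic contrast may need
adjustment on real micrographs, and the manual kernel choice matters
there.  Multi-grain patterns (two lattices in one image) and
rotation/scale-variant templates are out of scope, as is *correcting*
micrographs with the inverse warp — the package measures distortion, it
does not resample images.

## Calibration arithmetic

* Pixel size: known grating pitch × 1000 / mean basis length (nm/px); a
  >5 % difference between |g_r| and |g_l| attaches an anisotropy warning,
  since a square grating should measure equally in both directions.
* Section thickness: per cylindrical object, maximum diameter ÷ sections
  spanned; the summary is the unweighted mean with the sample standard
  deviation (no aggregation rule is canonical; objects are equally
  credible).  Diameters outside 100–2000 nm draw a plausibility warning.
* Geometry: side e = a·d, area f = e², volume g = b·c·f, voxels = c·d²,
  volume/hour = g/h, computed exactly and displayed at 4 significant
  figures (half-away rounding).  Because spec-sheet tables chain derived
  rows from already-rounded entries, the display layer also reports the
  volume recomputed from the rounded side; the exact value is
  authoritative and the per-hour figure divides the exact volume.
* Mosaic planning: tiles of extent tile_px × pixel size, effective stride
  (1 − overlap) × extent, counts by ceiling division per axis.

## Numerical notes and degenerate inputs

Affine fits reject <3 or collinear correspondences (SVD ratio 1e−9).
Polynomial fits reject underdetermined systems naming the minimum count.
Zero-variance kernels, empty thresholded maps, <3 triplets, empty
consensus sets, and isolated anchors raise typed errors that the CLI maps
to nonzero exits with the stage name.  RANSAC ties keep the first winner,
making results deterministic for a given seed; the seed is a mandatory
API parameter (CLI default 0).
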