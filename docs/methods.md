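# Methods

## Image model and assumptions

The segmentation assumes T2-weighted contrast ordering
CSF > cord > background and a cord that is a smooth tube roughly aligned
with the superior–inferior (SI) axis.  All volumes are handled in a
canonical (right–left, anterior–posterior, SI) axis order with 0-based
indices; an "axial slice" is always a plane perpendicular to the SI axis.
Working resolution is 0.3 mm isotropic, reached by tricubic resampling of
the (typically 0.9 mm isotropic) acquisition: at 0.3 mm the partial-volume
band at the cord/CSF interface is thin enough that the cross-sectional
area (CSA) error from boundary voxels stays well under the 2% the package
tests against.  Cubic overshoot is clipped at zero only — scanner units
have no natural upper bound.

## Per-slice double thresholding

The *first* threshold is Otsu's: the histogram spans `[min, max]` with 256
bins, candidate thresholds are the interior bin edges, class statistics
use exact per-bin value sums (not bin centers), pixels strictly above the
threshold are foreground, and ties resolve to the smallest maximizer.
This convention is implemented directly (and verified against exhaustive
search in the tests) because the downstream steps depend on its exact
boundary behaviour.

CSF selection takes the 8-connected foreground cluster of at least 50
pixels (at 0.3 mm) with the highest *mean* intensity — mean rather than
maximum, so a single bright speckle cannot hijack the choice.  Flood fill
uses 4-connected background (the standard dual of 8-connected
foreground).  When the ring is open, contrast enhancement clips the top
0.1% quantile and linearly restretches `[min, q]` onto the original range;
the retry loop is capped at 10 iterations (the loop needs a termination
guard; in practice clean slices use 0 iterations and pathological slices
either succeed within a few or cannot succeed at all).

The *second* (Losseff) threshold is the midpoint of the mean intensities
over the eroded cord and CSF seeds (disk of radius 3 px; erosion makes the
seeds conservative, so their means are nearly pure-tissue).  Classification
runs on the *original* slice — enhancement only serves CSF detection — and
is confined to the filled mask `M_F`, which restricts the decision to
inside the canal; the cord is the connected component containing the cord
seed's center of mass.  Boundary pixels claimed as cord by the second
threshold are removed from the CSF mask rather than the reverse: the
second threshold is the refinement step, and the opposite choice
systematically shaves majority-cord partial-volume pixels off the cord
(about −1.5% CSA on the noise-free phantom).

Failed slices are returned as data (`status="failed"`), never raised: the
3D correction is the designated repair path.

## 3D correction

Aberrant centers are detected on the **raw** centerline, before smoothing.
Two rules share the 15-voxel threshold (at 0.3 mm): the Euclidean residual
from a degree-5 polynomial fit of each in-plane coordinate against slice
index (degree 5 is high enough to follow cervical curvature yet far below
the slice count), and a first-difference rule that flags an interior point
only when both adjacent steps exceed the threshold *and* point in opposing
directions (an excursion that leaves the curve and comes back).  Detecting
after robust smoothing would be self-defeating: the robust smoother
suppresses exactly the isolated jumps that must be flagged, so a smoothed
curve never shows them.  Endpoints are covered by the residual rule alone,
since a single step cannot distinguish which of its two ends jumped.

Robust locally weighted regression (LOWESS: tricube distance weights over
the nearest 30% of points, local linear fits, two bisquare reweightings)
is implemented in-package.  Two non-obvious cases are handled explicitly:
when most points fit exactly (median residual 0), any point off the fit is
treated as an outlier rather than skipping the reweighting; and when
robustness weights annihilate an entire neighbourhood (a cluster of
rejected outliers), the bandwidth widens over the usable points instead of
returning the raw value.

Surviving masks are parameterized as 72 radii (every 5°, angle 0 toward
+col, counter-clockwise) about the **final** smoothed/interpolated
centerline — shape-preserving, and it guarantees the reconstructed
cross-sections are centered exactly on the curve the straightening step
follows.  The radius is the outermost 0.5-crossing of the mask along the
ray, sub-pixel by linear interpolation after a light Gaussian smoothing of
the binary mask (σ = 1 px), which averages out pixelation steps on rays
oblique to the boundary (bringing the worst-case radius error on a 2:1
ellipse from ≈0.55 px to ≈0.40 px).  Each angle's radius profile is
robust-LOWESS-smoothed across slices — this is what removes nerve-root
spurs confined to one or two slices — and cubic-spline interpolated at
missing slices (nearest-value extension at the ends; splines are not
extrapolated).  Contours are rasterized as 72-gon polygons (a 72-gon
covers 99.8% of the circumscribed circle's area).

## Straightening

Frames along the centerline are rotation-minimizing (parallel transport of
an initial normal), not Frenet: Frenet frames are undefined at zero
curvature and flip at inflections.  Output slices sample planes at uniform
arc length, so slice index is proportional to cord length — the property
length standardization relies on.  Intensities are tricubic, masks
nearest-neighbour.  In-plane samples outside the source field of view are
set to 0 and tallied in a warning; SI overhang of tilted end planes is
instead projected back along the end tangent, i.e. the cord is continued
straight past the operator's crop — physically the cord does continue, and
sampling emptiness there clips the end-slice masks and pulls their centers
off the grid center.  Re-straightening an already-straight volume is an
identity to within nearest-neighbour rounding.

The C2-level measurement averages `n` contiguous slabs of 3 mm (10 thin
slices each at 0.3 mm) with the most inferior slab centered on the
operator-chosen landmark slice; the landmark stays manual by design
(vertebral labeling is out of scope).

## Template construction

Subjects are straightened, FOV-centered and rescaled along SI to the
cohort's median length (whole-length standardization; per-vertebral-level
standardization is not implemented).  The template is the voxelwise mean
intensity smoothed with an anisotropic Gaussian, FWHM (0.3, 0.3, 0.6) mm in
(RL, AP, SI) order, σ = FWHM/(2√(2 ln 2)).  The probability map is the
plain voxelwise mean of the binary masks and is deliberately **not**
smoothed, so that its voxel sum times the voxel volume equals the cohort's
mean cord volume exactly — the invariant the tests assert.

## Synthetic phantoms

The generator renders a cord tube (default radius 4 mm) with a CSF ring
(2 mm) inside background, intensities 100/200/50, following a sinusoidal
sagittal-plane curve (amplitude in mm, period default 80 mm).  Partial
volume is modelled by 4× in-plane supersampling of the tissue indicators
followed by box-averaging — valid while the cord tangent stays near the SI
axis, which also bounds when the in-plane-disk rendering itself is valid.
Degradations apply in scanner order: Gaussian edge blur, a smooth
multiplicative bias field (random low-frequency cosine series rescaled to
span exactly the requested range, e.g. 0.8–1.2), and Rician magnitude
noise (the correct model for magnitude MR; default SNR 15, i.e.
σ = cord_intensity/15).  Ground truth (mask, centerline, analytic π·r²
CSA) is recorded before degradation, and a single integer seed determines
the output bit-for-bit.

Lesion models are minimal parametric stand-ins: focal atrophy
(cosine-tapered radius reduction), intramedullary hyperintensity (bright
in-plane disk inside the cord) and canal narrowing (ring-thickness
reduction).  The phantom does **not** emulate vertebrae, nerve roots, CSF
pulsation, coil-profile asymmetries or k-space artifacts.  Consequently,
passing phantom-based tests demonstrates the geometric and numerical
correctness of the chain and its robustness to noise, bias and curvature —
it does not certify accuracy on clinical images, where nerve roots and
pathology are the dominant failure modes.

## Problem sizes and numerical choices

Tests and the acceptance script use 200–210-slice phantoms (≈60 mm of
cord at 0.3 mm) with ≈95×95 in-plane grids — large enough that the
centerline statistics (LOWESS span 0.3, degree-5 fits) behave as on
clinical crops, while a full chain runs in seconds.  Other defaults:
histogram 256 bins; enhancement cap 10; discontinuity threshold 15 voxels;
ray sampling step 0.25 px; repair requires ≥5 usable slices
("unrecoverable" below that).  The bias-correction stand-in fits a
degree-3 polynomial to the log-intensity of voxels above the volume-wide
Otsu threshold, ridge-regularized (λ = 0.01 on normalized coordinates)
toward zero log-gain because the bright set is a thin tube and an
unconstrained polynomial can swing arbitrarily elsewhere; a hook accepts an
externally corrected volume, and this stand-in makes no claim to replicate
dedicated non-uniformity correctors.  Intensity normalization for template
building maps the 2nd–98th percentiles to [0, 1]; the percentile choice is
this package's own default.

## Known limitations

- Large T2-hyperintense lesions or a canal with almost no CSF can defeat
  both the per-slice method and the repair (no ring to find, no reliable
  neighbours) — the repair assumes failures are a minority of slices.
- Grey/white matter separation is impossible at this contrast and is not
  attempted.
- The polar contour representation is star-convex about the centerline;
  genuinely non-star-shaped cross-sections would be convexified.
- DICOM ingestion and automatic vertebral labeling are out of scope.
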