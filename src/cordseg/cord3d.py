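"""Step S7: assemble per-slice segmentations into a coherent 3D cord mask.

The cord is an anatomically smooth tube, so its centerline and its radial
profile vary slowly from slice to slice.  The correction exploits that:

1. extract the centerline (per-slice center of mass of the cord mask);
2. flag aberrant slices whose center jumps away from the polynomial trend
   or from its neighbours by more than a threshold (15 voxels at 0.3 mm)
   and discard their masks;
3. smooth the remaining centerline with robust locally weighted regression
   and fill missing slices by cubic-spline interpolation;
4. re-express every surviving mask as 72 radii (one per 5 degrees) around
   its center, smooth each angle's radius profile across slices with robust
   LOWESS (this is what suppresses nerve-root spurs), spline-fill the radii
   of missing slices, and rasterize the resulting polygons back to masks.

Slices whose mask had to be re-synthesized are marked ``repaired``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.draw import polygon as draw_polygon

from .dtbm_core import SliceSegmentation, compute_csa
from .volume_io import BinaryMask3D

__all__ = [
    "Centerline",
    "RadialContour",
    "CordSegmentation",
    "N_ANGLES",
    "extract_centerline",
    "robust_lowess",
    "detect_discontinuities",
    "interpolate_centerline",
    "mask_to_polar",
    "smooth_radii",
    "polar_to_mask",
    "correct_segmentation",
]

N_ANGLES = 72  # one radius every 5 degrees
_ANGLES = np.deg2rad(np.arange(N_ANGLES) * 5.0)


@dataclass
class Centerline:
    """Per-slice (row, col) cord centers in voxel coordinates.

    ``rows``/``cols`` are float arrays of length n_slices with NaN where the
    center is absent (failed or discarded slice).
    """

    rows: np.ndarray
    cols: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        self.cols = np.asarray(self.cols, dtype=np.float64)
        if self.rows.shape != self.cols.shape or self.rows.ndim != 1:
            raise ValueError("rows and cols must be 1D arrays of equal length")

    @property
    def n_slices(self) -> int:
        return self.rows.size

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.rows) & np.isfinite(self.cols)

    def points(self) -> np.ndarray:
        """(n, 2) array of (row, col), NaN where absent."""
        return np.stack([self.rows, self.cols], axis=1)


@dataclass
class RadialContour:
    """A cord cross-section as a center plus 72 radii sampled every 5 degrees,
    angle 0 pointing toward +col and increasing counter-clockwise."""

    center: tuple[float, float]
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=np.float64)
        if self.radii.shape != (N_ANGLES,):
            raise ValueError(f"expected {N_ANGLES} radii, got {self.radii.shape}")
        if not np.isfinite(self.radii).all() or (self.radii < 0).any():
            raise ValueError("radii must be finite and non-negative")


@dataclass
class CordSegmentation:
    """Final 3D segmentation: mask, centerline, per-slice CSA and provenance."""

    mask: BinaryMask3D
    centerline: Centerline
    csa_mm2: np.ndarray
    provenance: list[str]  # "segmented" | "repaired" per slice
    volume_mm3: float


def extract_centerline(masks: Sequence[Optional[np.ndarray]]) -> Centerline:
    """Center of mass of each available cord mask; NaN for absent slices."""
    rows = np.full(len(masks), np.nan)
    cols = np.full(len(masks), np.nan)
    any_ok = False
    for k, m in enumerate(masks):
        if m is None or not m.any():
            continue
        r, c = ndimage.center_of_mass(m.astype(bool))
        rows[k], cols[k] = r, c
        any_ok = True
    if not any_ok:
        raise ValueError("no non-empty slice masks: cannot extract centerline")
    return Centerline(rows, cols)


def robust_lowess(
    series: np.ndarray,
    span: float = 0.3,
    robust_iters: int = 2,
    x: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Robust locally weighted linear regression (LOWESS).

    Tricube distance weights over the ``span`` fraction of nearest points,
    local degree-1 fits, and ``robust_iters`` bisquare reweightings of the
    residuals so that isolated gross outliers (a displaced center, a
    nerve-root spur) barely influence the fit.  NaN entries are ignored for
    fitting and returned as NaN.
    """
    y = np.asarray(series, dtype=np.float64)
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if x is None:
        x = np.arange(y.size, dtype=np.float64)
    finite = np.isfinite(y)
    xf, yf = x[finite], y[finite]
    n = xf.size
    if n < 5:
        raise ValueError("robust LOWESS needs at least 5 points")
    k = max(2, int(np.ceil(span * n)))
    delta = np.ones(n)  # robustness weights
    fitted = np.empty(n)
    for _ in range(robust_iters + 1):
        usable = delta > 0
        for i in range(n):
            d = np.abs(xf - xf[i])
            # bandwidth over usable points only: a cluster of rejected
            # outliers must widen the window, not empty it
            du = d[usable]
            if du.size < 2:
                fitted[i] = yf[i]
                continue
            kk = min(k, du.size)
            h = np.partition(du, kk - 1)[kk - 1]
            if h <= 0:
                fitted[i] = np.average(yf[usable], weights=delta[usable])
                continue
            w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3 * delta
            sw = w.sum()
            if sw <= 0:
                fitted[i] = yf[i]
                continue
            xm = np.average(xf, weights=w)
            ym = np.average(yf, weights=w)
            sxx = np.sum(w * (xf - xm) ** 2)
            if sxx > 1e-12:
                b = np.sum(w * (xf - xm) * (yf - ym)) / sxx
            else:
                b = 0.0
            fitted[i] = ym + b * (xf[i] - xm)
        resid = yf - fitted
        s = np.median(np.abs(resid))
        if s <= 1e-12:
            # most points fit exactly; anything off the fit is an outlier
            scale = max(np.abs(yf).max(), 1.0)
            delta = (np.abs(resid) <= 1e-9 * scale).astype(float)
            if delta.sum() < 5:
                break
        else:
            delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    out = np.full_like(y, np.nan)
    out[finite] = fitted
    return out


def detect_discontinuities(
    centerline: Centerline, threshold_vox: float = 15.0, poly_degree: int = 5
) -> set[int]:
    """Flag slices whose center departs from the smooth course of the cord.

    Two complementary rules, both at the same threshold (15 voxels at the
    0.3 mm working grid): the Euclidean residual from a degree-5 polynomial
    fit of each in-plane coordinate against slice index, and the first
    difference between neighbouring present centers.  For the difference
    rule an interior slice is aberrant only when it jumps on *both* sides
    (an isolated spike), so a genuine step in the anatomy is not flagged
    twice.
    """
    if threshold_vox <= 0:
        raise ValueError("threshold must be positive")
    present = np.flatnonzero(centerline.present)
    if present.size == 0:
        return set()
    z = present.astype(float)
    deg = min(poly_degree, present.size - 1)
    flagged: set[int] = set()
    # residual rule
    res = np.zeros((present.size, 2))
    for j, series in enumerate((centerline.rows, centerline.cols)):
        coef = np.polyfit(z, series[present], deg)
        res[:, j] = series[present] - np.polyval(coef, z)
    dev = np.hypot(res[:, 0], res[:, 1])
    flagged.update(int(i) for i in present[dev > threshold_vox])
    # first-difference (derivative) rule: an isolated spike leaves the curve
    # and comes back, so both adjacent steps are large and anti-parallel
    pts = centerline.points()[present]
    diffs = np.diff(pts, axis=0)
    steps = np.linalg.norm(diffs, axis=1)
    for i in range(1, present.size - 1):
        if min(steps[i - 1], steps[i]) > threshold_vox:
            cosang = np.dot(diffs[i - 1], diffs[i]) / (steps[i - 1] * steps[i])
            if cosang < -0.5:
                flagged.add(int(present[i]))
    # endpoints have a single step and no return direction; the residual
    # rule above is what can flag them
    return flagged


def interpolate_centerline(centerline: Centerline) -> Centerline:
    """Fill absent centers: cubic spline inside the present range, nearest
    value beyond its ends.  Needs at least 4 present slices."""
    present = np.flatnonzero(centerline.present)
    if present.size < 4:
        raise ValueError("need at least 4 present centerline points")
    z = np.arange(centerline.n_slices, dtype=float)
    out_r = centerline.rows.copy()
    out_c = centerline.cols.copy()
    for series, out in ((centerline.rows, out_r), (centerline.cols, out_c)):
        spl = CubicSpline(present.astype(float), series[present])
        missing = ~centerline.present
        interior = missing & (z >= present[0]) & (z <= present[-1])
        out[interior] = spl(z[interior])
        out[missing & (z < present[0])] = series[present[0]]
        out[missing & (z > present[-1])] = series[present[-1]]
    return Centerline(out_r, out_c, smoothed=centerline.smoothed)


def mask_to_polar(
    mask: np.ndarray, center: tuple[float, float], step_px: float = 0.25
) -> RadialContour:
    """Sample the outer boundary of a mask along 72 rays from ``center``.

    The radius at each angle is the outermost 0.5-crossing of the mask along
    the ray, sub-pixel via linear interpolation.  The binary mask is first
    lightly Gaussian-smoothed (sigma = 1 px): the 0.5 level of the smoothed
    indicator averages out pixelation steps, which matters on rays oblique
    to the boundary.  Outermost crossing makes the measure robust to
    interior holes left by hypointense pixels.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    ci, cj = float(center[0]), float(center[1])
    ri, rj = int(round(ci)), int(round(cj))
    if not (0 <= ri < mask.shape[0] and 0 <= rj < mask.shape[1]) or not mask[ri, rj]:
        raise ValueError("center lies outside the mask")
    r_max = float(np.hypot(*mask.shape)) + 1.0
    r_samples = np.arange(step_px, r_max, step_px)
    maskf = ndimage.gaussian_filter(mask.astype(np.float64), 1.0)
    radii = np.empty(N_ANGLES)
    for a, theta in enumerate(_ANGLES):
        drow = -np.sin(theta)  # counter-clockwise with +col as angle 0
        dcol = np.cos(theta)
        rows = ci + r_samples * drow
        cols = cj + r_samples * dcol
        vals = ndimage.map_coordinates(
            maskf, np.stack([rows, cols]), order=1, mode="constant", cval=0.0
        )
        inside = vals >= 0.5
        if not inside.any():
            radii[a] = 0.0
            continue
        last = int(np.flatnonzero(inside)[-1])
        r = r_samples[last]
        if last + 1 < vals.size:
            v0, v1 = vals[last], vals[last + 1]
            if v0 > v1:  # refine the 0.5 crossing linearly
                r += step_px * (v0 - 0.5) / (v0 - v1)
        radii[a] = r
    return RadialContour(center=(ci, cj), radii=radii)


def smooth_radii(
    contours: Sequence[Optional[RadialContour]],
    centers: Optional[np.ndarray] = None,
    span: float = 0.3,
) -> list[RadialContour]:
    """Smooth each angle's radius profile across slices and fill gaps.

    Per angle independently: robust LOWESS across slice index (suppressing
    nerve-root spurs confined to one or two slices), then cubic-spline
    interpolation at missing slices, nearest-value extension at the ends.
    ``centers`` ((n, 2), required when any contour is missing) supplies the
    centers of the reconstructed contours; present contours keep their own.
    """
    n = len(contours)
    have = [c is not None for c in contours]
    idx = np.flatnonzero(have)
    if idx.size < 5:
        raise ValueError("need at least 5 slices with contours")
    rad = np.full((n, N_ANGLES), np.nan)
    for k in idx:
        rad[k] = contours[k].radii
    for a in range(N_ANGLES):
        col = rad[:, a]
        sm = robust_lowess(col, span=span)
        col[idx] = sm[idx]
        if idx.size != n:
            spl = CubicSpline(idx.astype(float), col[idx])
            z = np.arange(n, dtype=float)
            missing = np.array([not h for h in have])
            interior = missing & (z >= idx[0]) & (z <= idx[-1])
            col[interior] = spl(z[interior])
            col[missing & (z < idx[0])] = col[idx[0]]
            col[missing & (z > idx[-1])] = col[idx[-1]]
        rad[:, a] = np.clip(col, 0.0, None)
    out: list[RadialContour] = []
    for k in range(n):
        if have[k]:
            center = contours[k].center
        else:
            if centers is None:
                raise ValueError("centers required to rebuild missing contours")
            center = (float(centers[k, 0]), float(centers[k, 1]))
        out.append(RadialContour(center=center, radii=rad[k]))
    return out


def polar_to_mask(contour: RadialContour, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the 72-vertex polygon back to a binary mask: pixels whose
    centers lie inside the closed contour."""
    if np.all(contour.radii <= 0):
        raise ValueError("degenerate contour: all radii are zero")
    ci, cj = contour.center
    rows = ci - contour.radii * np.sin(_ANGLES)
    cols = cj + contour.radii * np.cos(_ANGLES)
    rr, cc = draw_polygon(rows, cols, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def segmentation_from_mask(
    mask: BinaryMask3D, smooth_span: Optional[float] = 0.3
) -> CordSegmentation:
    """Wrap an existing 3D cord mask as a CordSegmentation.

    The centerline is the per-slice center of mass, robust-LOWESS smoothed
    (``smooth_span``; pass None to skip) and spline-completed over empty
    slices; the mask itself is left untouched.  Useful for masks that are
    already coherent, e.g. ground truth or a straightened mask about to be
    re-straightened — raw center-of-mass jitter would otherwise tilt the
    resampling frames.
    """
    masks = [
        mask.data[:, :, k] if mask.data[:, :, k].any() else None
        for k in range(mask.data.shape[2])
    ]
    centerline = extract_centerline(masks)
    if smooth_span is not None and int(centerline.present.sum()) >= 5:
        centerline = Centerline(
            robust_lowess(centerline.rows, span=smooth_span),
            robust_lowess(centerline.cols, span=smooth_span),
            smoothed=True,
        )
    if not centerline.present.all():
        centerline = interpolate_centerline(centerline)
    in_plane = (mask.spacing[0], mask.spacing[1])
    csa = np.array(
        [compute_csa(mask.data[:, :, k], in_plane) for k in range(mask.data.shape[2])]
    )
    return CordSegmentation(
        mask=mask,
        centerline=centerline,
        csa_mm2=csa,
        provenance=["segmented"] * mask.data.shape[2],
        volume_mm3=mask.volume_mm3(),
    )


def correct_segmentation(
    slices: Sequence[SliceSegmentation],
    spacing: tuple[float, float, float],
    discontinuity_threshold_vox: float = 15.0,
    span: float = 0.3,
) -> CordSegmentation:
    """Repair a stack of per-slice segmentations into a smooth 3D cord mask.

    Aberrant centers are detected on the raw centerline (before smoothing:
    the robust smoother would otherwise hide exactly the jumps this step
    must find), their masks discarded; the centerline is then smoothed and
    spline-completed, every surviving mask is re-parameterized as 72 radii,
    the radii are smoothed per angle across slices and interpolated at
    missing slices, and the polygons are rasterized back on every slice.
    """
    slices = list(slices)
    n = len(slices)
    masks: list[Optional[np.ndarray]] = [
        s.m_sc if (s.status == "ok" and s.m_sc is not None and s.m_sc.any()) else None
        for s in slices
    ]
    ok_idx = [k for k, m in enumerate(masks) if m is not None]
    if len(ok_idx) < 5:
        raise ValueError(
            f"unrecoverable: only {len(ok_idx)} usable slices, need at least 5"
        )
    shape2d = masks[ok_idx[0]].shape

    raw = extract_centerline(masks)
    aberrant = detect_discontinuities(raw, discontinuity_threshold_vox)
    for k in aberrant:
        masks[k] = None
    if sum(m is not None for m in masks) < 5:
        raise ValueError("unrecoverable: too few slices after discontinuity removal")

    kept = extract_centerline(masks)
    sm_rows = robust_lowess(kept.rows, span=span)
    sm_cols = robust_lowess(kept.cols, span=span)
    centerline = interpolate_centerline(Centerline(sm_rows, sm_cols, smoothed=True))
    centers = centerline.points()

    # parameterize every surviving mask about the *final* centerline, so the
    # reconstructed cross-sections are centered exactly on the curve the
    # straightening step will follow
    contours: list[Optional[RadialContour]] = []
    for k in range(n):
        if masks[k] is None:
            contours.append(None)
            continue
        try:
            contours.append(mask_to_polar(masks[k], (centers[k, 0], centers[k, 1])))
        except ValueError:
            masks[k] = None
            contours.append(None)
    if sum(m is not None for m in masks) < 5:
        raise ValueError("unrecoverable: too few slices with usable contours")
    smoothed = smooth_radii(contours, centers=centers, span=span)

    final = np.zeros((shape2d[0], shape2d[1], n), dtype=np.uint8)
    csa = np.zeros(n)
    provenance: list[str] = []
    in_plane = (spacing[0], spacing[1])
    for k in range(n):
        m = polar_to_mask(smoothed[k], shape2d)
        final[:, :, k] = m
        csa[k] = compute_csa(m, in_plane)
        provenance.append("segmented" if masks[k] is not None else "repaired")

    mask3d = BinaryMask3D(final, spacing)
    return CordSegmentation(
        mask=mask3d,
        centerline=centerline,
        csa_mm2=csa,
        provenance=provenance,
        volume_mm3=mask3d.volume_mm3(),
    )
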