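"""NIfTI volume handling: load/save, ROI cropping, isotropic resampling,
intensity normalization and a polynomial bias-field correction.

All in-memory volumes are kept in a canonical axis order
(right-left, anterior-posterior, superior-inferior), so that "axial slice k"
always means the plane ``data[:, :, k]`` perpendicular to the SI axis.
Slice indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Callable

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "IntensityVolume",
    "BinaryMask3D",
    "RegionOfInterest",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "crop_to_roi",
    "resample_isotropic",
    "normalize_intensity",
    "correct_bias_field",
]

CANONICAL_AXES = ("RL", "AP", "SI")


@dataclass
class IntensityVolume:
    """A 3D scalar MR volume with millimetre voxel spacing.

    Axes are ordered (RL, AP, SI): axial slices are ``data[:, :, k]`` and the
    SI index ``k`` increases from inferior to superior.  Intensities are in
    arbitrary scanner units and must be finite.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = CANONICAL_AXES
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D scalar volume, got {self.data.ndim}D data"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        if sorted(self.axes) != sorted(CANONICAL_AXES):
            raise ValueError(
                f"axis roles must be a permutation of {CANONICAL_AXES}, got {self.axes}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        """Number of axial slices (extent along the SI axis)."""
        return self.data.shape[self.axes.index("SI")]

    def axial_slice(self, k: int) -> np.ndarray:
        """The k-th axial slice (assumes canonical axis order)."""
        return self.data[:, :, k]

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing[0], self.spacing[1]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask3D:
    """A 3D binary mask paired with a volume: same shape, same spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniques = np.unique(arr)
        if not np.isin(uniques, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D data")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))


@dataclass(frozen=True)
class RegionOfInterest:
    """Inclusive SI slice range selected by the operator.

    Replaces the two mouse clicks marking the upper and lower limits of the
    cord region: two integer slice indices along the SI axis.
    """

    slice_lo: int
    slice_hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.slice_lo < self.slice_hi):
            raise ValueError(
                f"require 0 <= slice_lo < slice_hi, got ({self.slice_lo}, {self.slice_hi})"
            )

    def validate(self, n_slices: int) -> None:
        if self.slice_hi >= n_slices:
            raise ValueError(
                f"ROI upper slice {self.slice_hi} out of bounds for {n_slices} slices"
            )


def _canonicalize(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def load_volume(path: str | Path) -> IntensityVolume:
    """Load a 3D NIfTI volume, reoriented to canonical (RL, AP, SI) axes.

    Raises a descriptive error for missing files, non-3D data and degenerate
    voxel spacing; non-finite voxels are rejected rather than silently kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = _canonicalize(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(
            f"expected 3D scalar volume in {path}, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    return IntensityVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        axes=CANONICAL_AXES,
        affine=np.asarray(img.affine),
    )


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_volume(vol: IntensityVolume, path: str | Path) -> None:
    """Write an IntensityVolume as float32 NIfTI-1."""
    affine = vol.affine if vol.affine is not None else _default_affine(vol.spacing)
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> BinaryMask3D:
    """Load a binary mask; any nonzero voxel counts as foreground."""
    vol = load_volume(path)
    return BinaryMask3D(
        data=(vol.data > 0.5).astype(np.uint8),
        spacing=vol.spacing,
        affine=vol.affine,
    )


def save_mask(mask: BinaryMask3D, path: str | Path) -> None:
    affine = mask.affine if mask.affine is not None else _default_affine(mask.spacing)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def crop_to_roi(vol: IntensityVolume, roi: RegionOfInterest) -> IntensityVolume:
    """Crop the volume to the operator-selected SI slice range (inclusive)."""
    roi.validate(vol.n_slices)
    return replace(vol, data=vol.data[:, :, roi.slice_lo : roi.slice_hi + 1].copy())


def resample_isotropic(vol: IntensityVolume, target_mm: float = 0.3) -> IntensityVolume:
    """Resample to an isotropic grid by tricubic interpolation.

    The working resolution for segmentation defaults to 0.3 mm, fine enough
    that partial-volume voxels at the cord/CSF interface contribute little to
    the cross-sectional area error.  Cubic overshoot below zero is clipped
    (scanner magnitudes are non-negative); no upper clip is applied.
    """
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    zoom = tuple(s / target_mm for s in vol.spacing)
    out = ndimage.zoom(vol.data, zoom, order=3, mode="nearest", grid_mode=True)
    np.clip(out, 0.0, None, out=out)
    return IntensityVolume(
        data=out,
        spacing=(target_mm, target_mm, target_mm),
        axes=vol.axes,
        affine=None,
    )


def normalize_intensity(
    vol: IntensityVolume, mode: str = "percentile-rescale"
) -> IntensityVolume:
    """Map the 2nd..98th intensity percentiles onto [0, 1], clipping outside.

    A monotone, order-preserving rescale used before pooling subjects into a
    template, so that scanner-unit differences between acquisitions do not
    dominate the average.
    """
    if mode != "percentile-rescale":
        raise ValueError(f"unknown normalization mode: {mode!r}")
    lo, hi = np.percentile(vol.data, [2.0, 98.0])
    if hi <= lo:
        raise ValueError("no dynamic range: volume is (nearly) constant")
    out = np.clip((vol.data - lo) / (hi - lo), 0.0, 1.0)
    return replace(vol, data=out)


def correct_bias_field(
    vol: IntensityVolume,
    order: int = 3,
    external: Optional[Callable[[IntensityVolume], IntensityVolume]] = None,
) -> IntensityVolume:
    """Remove a smooth multiplicative intensity gain (B1 non-uniformity).

    Fits a low-order 3D polynomial to the log-intensity of bright voxels
    (above the volume-wide Otsu threshold, i.e. predominantly CSF) and divides
    the fitted gain out, preserving the mean intensity.  ``external`` is a
    hook for substituting a dedicated bias-correction tool: when given, it is
    called with the volume and its result returned unchanged.
    """
    if external is not None:
        return external(vol)
    if order < 1:
        raise ValueError("polynomial order must be >= 1")
    from skimage.filters import threshold_otsu

    data = vol.data
    if data.max() <= 0:
        raise ValueError("no bright voxels: volume is non-positive")
    thr = threshold_otsu(data)
    bright = data > thr
    if not bright.any():
        raise ValueError("empty bright-voxel set above Otsu threshold")

    # Fit log-gain on bright voxels only: the CSF compartment is the closest
    # thing to a constant-intensity reference in these images.  The fit is
    # ridge-regularized toward a constant (zero log-gain): the bright set is
    # a thin tube, and an unpenalized polynomial constrained only there can
    # swing arbitrarily over the rest of the volume.
    coords = [np.linspace(-1.0, 1.0, n) for n in data.shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    powers = [
        (i, j, k)
        for i in range(order + 1)
        for j in range(order + 1)
        for k in range(order + 1)
        if 0 < i + j + k <= order
    ]
    cols_bright = np.stack(
        [gx[bright] ** i * gy[bright] ** j * gz[bright] ** k for i, j, k in powers],
        axis=1,
    )
    target = np.log(data[bright])
    target -= target.mean()
    n_b = cols_bright.shape[0]
    lam = 1e-2
    coef = np.linalg.solve(
        cols_bright.T @ cols_bright / n_b + lam * np.eye(len(powers)),
        cols_bright.T @ target / n_b,
    )

    log_gain = np.zeros_like(data)
    for c, (i, j, k) in zip(coef, powers):
        log_gain += c * gx**i * gy**j * gz**k
    gain = np.exp(log_gain - log_gain.mean())
    corrected = data / gain
    # preserve overall mean intensity
    corrected *= data.mean() / corrected.mean()
    return replace(vol, data=corrected)
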