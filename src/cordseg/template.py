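"""Cervical cord template and tissue-probability map construction.

Straightened, FOV-centered subjects are standardized to a common length
(the cohort median, in slices) by rescaling the SI axis only — cubic for
intensities, nearest-neighbour for masks, so in-plane cross-sections are
untouched.  The template is the voxelwise mean intensity smoothed with an
anisotropic 3D Gaussian (FWHM 0.3 x 0.3 x 0.6 mm by default); the
probability map is the unsmoothed voxelwise mean of the binary masks, so
each voxel holds the fraction of subjects whose cord covers it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .straighten import StraightenedVolume
from .volume_io import BinaryMask3D

__all__ = [
    "CordTemplate",
    "standardize_length",
    "median_length",
    "build_template",
    "misseg_error_rate",
    "FWHM_TO_SIGMA",
]

# sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class CordTemplate:
    """Cohort-average straightened cord: smoothed mean image plus the
    voxelwise probability (in [0, 1]) of belonging to the cord."""

    mean_image: np.ndarray
    probability_map: np.ndarray
    n_subjects: int
    standard_length_slices: int
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.mean_image.shape != self.probability_map.shape:
            raise ValueError("mean image and probability map shapes differ")
        pm = self.probability_map
        if pm.min() < 0 or pm.max() > 1:
            raise ValueError("probability map values must lie in [0, 1]")

    def mean_cord_volume_mm3(self) -> float:
        """Probability-weighted cord volume = mean cord volume of the cohort."""
        return float(self.probability_map.sum()) * float(np.prod(self.spacing))


def median_length(lengths: Sequence[int]) -> int:
    """Cohort standard length: the (lower) median of the subject lengths."""
    return int(np.percentile(np.asarray(lengths), 50, method="lower"))


def _rescale_si(data: np.ndarray, target_slices: int, order: int) -> np.ndarray:
    n = data.shape[2]
    # sample positions that map the input extent onto exactly target_slices
    z = (np.arange(target_slices) + 0.5) * n / target_slices - 0.5
    z = np.clip(z, 0, n - 1)
    ii, jj, zz = np.meshgrid(
        np.arange(data.shape[0], dtype=float),
        np.arange(data.shape[1], dtype=float),
        z,
        indexing="ij",
    )
    return ndimage.map_coordinates(
        data.astype(float), np.stack([ii, jj, zz]), order=order, mode="nearest"
    )


def standardize_length(
    straight: StraightenedVolume, mask: BinaryMask3D, target_slices: int
) -> tuple[StraightenedVolume, BinaryMask3D]:
    """Rescale the SI axis to exactly ``target_slices`` slices.

    Intensities are interpolated cubically (clipped at 0), masks by nearest
    neighbour; in-plane geometry, and hence per-slice CSA, is preserved.
    """
    if target_slices < 2:
        raise ValueError("target length must be at least 2 slices")
    if straight.n_slices < 2:
        raise ValueError("degenerate input: fewer than 2 slices")
    data = np.clip(_rescale_si(straight.data, target_slices, order=3), 0.0, None)
    m = _rescale_si(mask.data, target_slices, order=0).astype(np.uint8)
    arc = np.interp(
        np.linspace(0, straight.n_slices - 1, target_slices),
        np.arange(straight.n_slices),
        straight.arc_length_mm,
    )
    out_vol = StraightenedVolume(
        data=data,
        spacing=straight.spacing,
        center_row=straight.center_row,
        center_col=straight.center_col,
        arc_length_mm=arc,
    )
    return out_vol, BinaryMask3D(m, mask.spacing)


def build_template(
    cohort: Sequence[tuple[StraightenedVolume, BinaryMask3D]],
    fwhm_mm: tuple[float, float, float] = (0.3, 0.3, 0.6),
) -> CordTemplate:
    """Average a standardized cohort into a template and probability map.

    ``mean_image`` is the voxelwise mean of the intensity volumes smoothed
    with an anisotropic Gaussian (sigma = FWHM x 0.4247 per axis, converted
    to voxels via the spacing); ``probability_map`` is the plain voxelwise
    mean of the binary masks and is deliberately left unsmoothed so that its
    voxel sum times the voxel volume equals the cohort mean cord volume.
    """
    if len(cohort) < 2:
        raise ValueError("template construction needs at least 2 subjects")
    shapes = {v.data.shape for v, _ in cohort} | {m.data.shape for _, m in cohort}
    if len(shapes) != 1:
        raise ValueError(f"cohort shapes differ after standardization: {shapes}")
    spacing = cohort[0][0].spacing
    mean_img = np.mean([v.data for v, _ in cohort], axis=0)
    sigma_vox = tuple(f * FWHM_TO_SIGMA / s for f, s in zip(fwhm_mm, spacing))
    mean_img = ndimage.gaussian_filter(mean_img, sigma=sigma_vox, mode="nearest")
    prob = np.mean([m.data.astype(float) for _, m in cohort], axis=0)
    return CordTemplate(
        mean_image=mean_img,
        probability_map=prob,
        n_subjects=len(cohort),
        standard_length_slices=cohort[0][0].n_slices,
        spacing=spacing,
    )


def misseg_error_rate(n_missegmented: int, n_total: int) -> float:
    """Percentage of axial slices the operator had to adjust:
    100 * mis-segmented / total."""
    if n_total <= 0:
        raise ValueError("total slice count must be positive")
    if not (0 <= n_missegmented <= n_total):
        raise ValueError("mis-segmented count out of range")
    return 100.0 * n_missegmented / n_total
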