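"""Per-axial-slice double-threshold cord segmentation (steps S1-S6).

The method exploits the T2 contrast ordering CSF > cord > background:

S1  Otsu's threshold (the *first* threshold) picks the brightest pixels,
    predominantly CSF.
S2  The connected cluster with the highest mean intensity and at least
    ``min_size`` pixels becomes the CSF mask ``M_CSF``.
S3  Flood-filling the interior of the CSF ring yields ``M_F``.
S4a If the ring is open (nothing to fill), global contrast is enhanced by
    truncating the top 0.1% of the histogram and S1-S3 are retried.
S4b Otherwise ``M_F - M_CSF`` is the inner region: the cord mask ``M_SC``.
S5  Both masks are eroded (disk, radius 3 px) to obtain conservative seeds.
S6  The Losseff threshold-based step: the midpoint of the mean seed
    intensities (the *second* threshold) classifies pixels inside ``M_F``
    into cord vs CSF; the cross-sectional area (CSA) is the cord pixel count
    times the pixel area.

Failed slices are data, not exceptions: the 3D correction step repairs them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "AxialSlice",
    "SliceSegmentation",
    "DtbmConfig",
    "otsu_threshold",
    "extract_csf_mask",
    "flood_fill",
    "enhance_contrast",
    "erode_mask",
    "losseff_segment",
    "segment_slice",
    "segment_volume",
    "compute_csa",
    "CsfNotFound",
]


@dataclass
class AxialSlice:
    """A single axial plane of intensities with in-plane mm spacing."""

    data: np.ndarray
    spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("axial slice must be 2D")
        if not np.isfinite(self.data).all():
            raise ValueError("axial slice contains non-finite values")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("in-plane spacing must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[0] * self.spacing[1]


@dataclass
class SliceSegmentation:
    """Products of S1-S6 for one axial slice."""

    status: str  # "ok" | "failed"
    m_csf: Optional[np.ndarray] = None
    m_f: Optional[np.ndarray] = None
    m_sc: Optional[np.ndarray] = None
    otsu_threshold: float = np.nan
    losseff_threshold: float = np.nan
    enhancement_iterations: int = 0
    csa_mm2: float = np.nan
    failure_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("ok", "failed"):
            raise ValueError(f"status must be 'ok' or 'failed', got {self.status!r}")
        if self.status == "ok":
            assert self.m_sc is not None and self.m_f is not None
            if (self.m_sc & ~self.m_f).any():
                raise ValueError("cord mask must lie inside the filled mask")
            if (self.m_sc & self.m_csf).any():
                raise ValueError("cord and CSF masks must be disjoint")


@dataclass(frozen=True)
class DtbmConfig:
    """Tunables of the per-slice method, interpreted at the 0.3 mm working
    resolution (the defaults come from that grid)."""

    bins: int = 256
    min_csf_size: int = 50
    erosion_radius_px: int = 3
    upper_frac: float = 0.001
    max_enhance: int = 10


class CsfNotFound(RuntimeError):
    """No sufficiently large bright cluster: the CSF ring was not detected."""


def _histogram_stats(data: np.ndarray, bins: int):
    lo, hi = float(data.min()), float(data.max())
    counts, edges = np.histogram(data, bins=bins, range=(lo, hi))
    sums, _ = np.histogram(data, bins=bins, range=(lo, hi), weights=data)
    return counts, sums, edges


def otsu_threshold(slc: AxialSlice | np.ndarray, bins: int = 256) -> float:
    """Otsu's global threshold: the bin edge maximizing between-class variance.

    The histogram spans [min, max] with ``bins`` bins; candidate thresholds
    are the interior bin edges, pixels strictly above the threshold are
    foreground, and class statistics use the exact pixel values accumulated
    per bin (not bin centers).  Ties resolve to the smallest threshold.
    """
    data = slc.data if isinstance(slc, AxialSlice) else np.asarray(slc, float)
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    if data.max() == data.min():
        raise ValueError("no contrast: slice is constant")
    counts, sums, edges = _histogram_stats(data.ravel(), bins)
    n = counts.sum()
    total = sums.sum()
    # split after bin k: class0 = bins[0..k], class1 = bins[k+1..]
    n0 = np.cumsum(counts)[:-1]
    s0 = np.cumsum(sums)[:-1]
    n1 = n - n0
    s1 = total - s0
    valid = (n0 > 0) & (n1 > 0)
    sigma_b = np.full(bins - 1, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b[valid] = (
            n0[valid] * n1[valid] * (s0[valid] / n0[valid] - s1[valid] / n1[valid]) ** 2
        )
    best = int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximizer
    return float(edges[best + 1])


def extract_csf_mask(
    slc: AxialSlice, fg: np.ndarray, min_size: int = 50
) -> np.ndarray:
    """S2: among 8-connected foreground clusters of at least ``min_size``
    pixels, return the one with the highest mean intensity (the CSF)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    labels, n_comp = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    if n_comp == 0:
        raise CsfNotFound("no foreground clusters")
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_comp + 1))
    candidates = np.flatnonzero(sizes >= min_size) + 1
    if candidates.size == 0:
        raise CsfNotFound(f"no cluster of >= {min_size} connected pixels")
    means = ndimage.mean(slc.data, labels, index=candidates)
    winner = candidates[int(np.argmax(means))]
    return (labels == winner).astype(bool)


def flood_fill(m_csf: np.ndarray) -> np.ndarray:
    """S3: fill the interior of the CSF ring.

    Background 4-connectivity: any background region not reachable from the
    slice border becomes foreground, so an open (C-shaped) ring fills
    nothing while a closed annulus becomes a disk.
    """
    return ndimage.binary_fill_holes(m_csf.astype(bool))


def enhance_contrast(slc: AxialSlice, upper_frac: float = 0.001) -> AxialSlice:
    """S4a: truncate the top ``upper_frac`` of the histogram and restretch.

    Values above the (1 - upper_frac) quantile q are clipped to q and
    [min, q] is linearly rescaled back onto the original [min, max]; the map
    is monotone non-decreasing and boosts the relative contrast of the
    sub-maximal CSF ring.
    """
    if not (0 < upper_frac < 1):
        raise ValueError("upper_frac must be in (0, 1)")
    data = slc.data
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise ValueError("no contrast: slice is constant")
    q = float(np.quantile(data, 1.0 - upper_frac))
    if q >= hi:
        return AxialSlice(data.copy(), slc.spacing)
    if q <= lo:
        return AxialSlice(data.copy(), slc.spacing)
    clipped = np.minimum(data, q)
    rescaled = lo + (clipped - lo) * (hi - lo) / (q - lo)
    return AxialSlice(rescaled, slc.spacing)


def erode_mask(mask: np.ndarray, radius_px: int = 3) -> np.ndarray:
    """S5: morphological erosion with the discrete disk {i^2+j^2 <= r^2}."""
    if radius_px < 1:
        raise ValueError("erosion radius must be >= 1")
    selem = disk(radius_px)
    return ndimage.binary_erosion(mask.astype(bool), structure=selem)


def losseff_segment(
    slc: AxialSlice,
    cord_seed: np.ndarray,
    csf_seed: np.ndarray,
    domain: np.ndarray,
) -> tuple[np.ndarray, float]:
    """S6: classify pixels at the midpoint of the mean seed intensities.

    T = (mean over cord seed + mean over CSF seed) / 2; within ``domain``
    (the filled mask) pixels darker than T are cord candidates, and the
    connected component containing the cord seed's center of mass is the
    cord mask.
    """
    cord_seed = cord_seed.astype(bool)
    csf_seed = csf_seed.astype(bool)
    if not cord_seed.any() or not csf_seed.any():
        raise ValueError("seed-empty: both seeds must be non-empty")
    t = 0.5 * (slc.data[cord_seed].mean() + slc.data[csf_seed].mean())
    cand = domain.astype(bool) & (slc.data < t)
    labels, n_comp = ndimage.label(cand, structure=np.ones((3, 3), dtype=bool))
    if n_comp == 0:
        return np.zeros_like(cand), t
    com = ndimage.center_of_mass(cord_seed)
    ci, cj = int(round(com[0])), int(round(com[1]))
    lab = labels[ci, cj] if (0 <= ci < cand.shape[0] and 0 <= cj < cand.shape[1]) else 0
    if lab == 0:
        # center of mass fell outside the candidate set; take the component
        # with the largest overlap with the seed
        overlaps = ndimage.sum_labels(cord_seed, labels, index=np.arange(1, n_comp + 1))
        if overlaps.max() == 0:
            return np.zeros_like(cand), t
        lab = int(np.argmax(overlaps)) + 1
    return (labels == lab), t


def segment_slice(slc: AxialSlice, cfg: DtbmConfig = DtbmConfig()) -> SliceSegmentation:
    """Run S1-S6 with the S4a contrast-enhancement retry loop.

    Never raises: an unsegmentable slice comes back with ``status='failed'``
    so the 3D correction step can repair it from its neighbours.
    """
    original = slc
    work = slc
    for iteration in range(cfg.max_enhance + 1):
        try:
            thr = otsu_threshold(work, cfg.bins)
        except ValueError:
            return SliceSegmentation(
                status="failed",
                enhancement_iterations=iteration,
                failure_reason="no-contrast",
            )
        fg = work.data > thr
        try:
            m_csf = extract_csf_mask(work, fg, cfg.min_csf_size)
        except CsfNotFound:
            work = enhance_contrast(work, cfg.upper_frac)
            continue
        m_f = flood_fill(m_csf)
        inner = m_f & ~m_csf
        if not inner.any():  # S4a: ring not closed, nothing was filled
            work = enhance_contrast(work, cfg.upper_frac)
            continue
        cord_seed = erode_mask(inner, cfg.erosion_radius_px)
        csf_seed = erode_mask(m_csf, cfg.erosion_radius_px)
        if not cord_seed.any() or not csf_seed.any():
            return SliceSegmentation(
                status="failed",
                m_csf=m_csf,
                m_f=m_f,
                otsu_threshold=thr,
                enhancement_iterations=iteration,
                failure_reason="erosion-annihilated-seed",
            )
        # S6 classifies the *initial* image: enhancement only helps S1-S3
        m_sc, t2 = losseff_segment(original, cord_seed, csf_seed, m_f)
        # boundary pixels the second threshold claims as cord leave the CSF
        # mask, keeping the two classes disjoint
        m_csf = m_csf & ~m_sc
        if not m_sc.any():
            return SliceSegmentation(
                status="failed",
                m_csf=m_csf,
                m_f=m_f,
                otsu_threshold=thr,
                losseff_threshold=t2,
                enhancement_iterations=iteration,
                failure_reason="empty-cord-mask",
            )
        return SliceSegmentation(
            status="ok",
            m_csf=m_csf,
            m_f=m_f,
            m_sc=m_sc,
            otsu_threshold=thr,
            losseff_threshold=t2,
            enhancement_iterations=iteration,
            csa_mm2=compute_csa(m_sc, original.spacing),
        )
    return SliceSegmentation(
        status="failed",
        enhancement_iterations=cfg.max_enhance,
        failure_reason="enhancement-exhausted",
    )


def segment_volume(vol, cfg: DtbmConfig = DtbmConfig()) -> list[SliceSegmentation]:
    """Apply the per-slice method to every axial slice of a volume."""
    sp = vol.in_plane_spacing
    return [
        segment_slice(AxialSlice(vol.axial_slice(k), sp), cfg)
        for k in range(vol.n_slices)
    ]


def compute_csa(mask: np.ndarray, spacing: tuple[float, float]) -> float:
    """Cross-sectional area in mm^2: pixel count times pixel area."""
    return float(np.count_nonzero(mask)) * spacing[0] * spacing[1]
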