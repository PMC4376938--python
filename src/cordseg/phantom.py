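"""Synthetic cord MR phantoms with exact ground truth.

The phantom emulates the contrast the double-threshold method relies on: a
dark cord tube (T2-hypointense relative to fluid) surrounded by a bright
CSF ring inside darker tissue background, following a smooth sagittal-plane
sinusoidal curve.  Degradations are applied in scanner order — partial
volume (supersampled rendering), Gaussian edge blur, a smooth multiplicative
bias field, Rician magnitude noise — while the ground-truth mask, centerline
and analytic per-slice CSA are recorded before any degradation.

Everything is driven by a single integer seed: identical specs and seeds
produce bit-identical volumes.

What it does not emulate: vertebrae, nerve roots, CSF pulsation artifacts
and k-space effects; lesions are minimal parametric stand-ins (focal
atrophy, intramedullary hyperintensity, CSF-space narrowing), not
biophysical simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .cord3d import Centerline
from .dtbm_core import SliceSegmentation, compute_csa
from .volume_io import BinaryMask3D, IntensityVolume

__all__ = [
    "PhantomSpec",
    "PhantomInstance",
    "FocalAtrophy",
    "Hyperintensity",
    "NarrowCanal",
    "generate_phantom",
    "inject_failures",
]


@dataclass(frozen=True)
class FocalAtrophy:
    """Local thinning of the cord: radius reduced by ``radius_reduction_mm``
    over an SI extent centered at ``center_mm`` (cosine-tapered)."""

    center_mm: float
    extent_mm: float
    radius_reduction_mm: float


@dataclass(frozen=True)
class Hyperintensity:
    """Bright intramedullary focus (T2 hyperintense lesion) of in-plane
    radius ``radius_mm`` over an SI extent around ``center_mm``."""

    center_mm: float
    extent_mm: float
    radius_mm: float = 2.0
    intensity: float = 180.0


@dataclass(frozen=True)
class NarrowCanal:
    """CSF-space narrowing: ring thickness reduced to ``thickness_mm`` over
    an SI extent around ``center_mm`` (cosine-tapered)."""

    center_mm: float
    extent_mm: float
    thickness_mm: float = 0.6


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and degradation parameters of a synthetic cord.

    Defaults mirror a cervical T2 acquisition resampled to the 0.3 mm
    working grid: 4 mm cord radius, 2 mm CSF ring, intensity ordering
    CSF (200) > cord (100) > background (50), and — when enabled — Rician
    noise at SNR 15 and a 0.8-1.2x smooth bias field.
    """

    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)
    n_slices: int = 200
    shape_in_plane: Optional[tuple[int, int]] = None
    cord_radius_mm: float | Callable[[np.ndarray], np.ndarray] = 4.0
    csf_thickness_mm: float = 2.0
    curve_amplitude_mm: float = 0.0
    curve_period_mm: float = 80.0
    cord_intensity: float = 100.0
    csf_intensity: float = 200.0
    background_intensity: float = 50.0
    edge_blur_mm: float = 0.0
    noise_snr: Optional[float] = None
    bias_range: Optional[tuple[float, float]] = None
    lesions: tuple = ()
    supersample: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.csf_intensity > self.cord_intensity > self.background_intensity
        ):
            raise ValueError(
                "T2 contrast polarity requires CSF > cord > background intensity"
            )
        if any(s <= 0 for s in self.spacing) or self.n_slices < 1:
            raise ValueError("invalid grid geometry")
        if self.csf_thickness_mm <= 0:
            raise ValueError("CSF ring thickness must be positive")


@dataclass
class PhantomInstance:
    """A rendered phantom: degraded volume plus pristine ground truth."""

    volume: IntensityVolume
    truth_mask: BinaryMask3D
    truth_centerline: Centerline
    truth_csa_mm2: np.ndarray
    spec: PhantomSpec


def _radius_profile(spec: PhantomSpec, z_mm: np.ndarray) -> np.ndarray:
    if callable(spec.cord_radius_mm):
        r = np.asarray(spec.cord_radius_mm(z_mm), dtype=float)
    else:
        r = np.full_like(z_mm, float(spec.cord_radius_mm))
    for les in spec.lesions:
        if isinstance(les, FocalAtrophy):
            r = r - les.radius_reduction_mm * _taper(z_mm, les.center_mm, les.extent_mm)
    if (r <= 0).any():
        raise ValueError("cord radius must remain positive everywhere")
    return r


def _thickness_profile(spec: PhantomSpec, z_mm: np.ndarray) -> np.ndarray:
    t = np.full_like(z_mm, spec.csf_thickness_mm)
    for les in spec.lesions:
        if isinstance(les, NarrowCanal):
            w = _taper(z_mm, les.center_mm, les.extent_mm)
            t = t * (1 - w) + les.thickness_mm * w
    if (t <= 0).any():
        raise ValueError("CSF ring thickness must remain positive")
    return t


def _taper(z_mm: np.ndarray, center: float, extent: float) -> np.ndarray:
    """Cosine window in [0, 1], 1 at the lesion center, 0 outside extent."""
    u = np.abs(z_mm - center) / (extent / 2.0)
    return np.where(u < 1, 0.5 * (1 + np.cos(np.pi * u)), 0.0)


def _default_shape(spec: PhantomSpec) -> tuple[int, int]:
    z = np.arange(spec.n_slices) * spec.spacing[2]
    r_max = float(_radius_profile(spec, z).max())
    half_mm = r_max + spec.csf_thickness_mm + abs(spec.curve_amplitude_mm) + 3.0
    h0 = int(np.ceil(half_mm / spec.spacing[0]))
    h1 = int(np.ceil(half_mm / spec.spacing[1]))
    return 2 * h0 + 1, 2 * h1 + 1


def _bias_field(
    shape: tuple[int, int, int], lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative gain with values spanning exactly [lo, hi]:
    a random low-frequency cosine series rescaled to the requested range."""
    coords = [np.linspace(0, 1, n) for n in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    g = np.zeros(shape)
    for _ in range(3):
        fx, fy, fz = rng.uniform(0.5, 1.5, size=3)
        px, py, pz = rng.uniform(0, 2 * np.pi, size=3)
        g += rng.normal() * np.cos(np.pi * (fx * gx + px)) * np.cos(
            np.pi * (fy * gy + py)
        ) * np.cos(np.pi * (fz * gz + pz))
    gmin, gmax = g.min(), g.max()
    if gmax - gmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (g - gmin) * (hi - lo) / (gmax - gmin)


def generate_phantom(spec: PhantomSpec) -> PhantomInstance:
    """Render a phantom according to ``spec``.

    Partial volume at tissue boundaries is modelled by supersampling each
    axial plane ``supersample`` times per axis and box-averaging the tissue
    indicator down to the voxel grid, so boundary voxels carry intermediate
    intensities just as in resampled MR data.  The tube is rendered as an
    in-plane disk around the (possibly curved) centerline — a good model
    while the cord tangent stays near the SI axis.
    """
    sp = spec.spacing
    n0, n1 = spec.shape_in_plane or _default_shape(spec)
    nz = spec.n_slices
    ss = spec.supersample
    if min(sp[0], sp[1]) > spec.csf_thickness_mm:
        import warnings

        warnings.warn("CSF ring thinner than one voxel; segmentation may fail")

    z_mm = np.arange(nz) * sp[2]
    radii = _radius_profile(spec, z_mm)
    thick = _thickness_profile(spec, z_mm)
    c_row = np.full(nz, (n0 - 1) / 2.0)
    c_col = (n1 - 1) / 2.0 + (
        spec.curve_amplitude_mm / sp[1]
    ) * np.sin(2 * np.pi * z_mm / spec.curve_period_mm)

    # supersampled in-plane coordinates (voxel units)
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    rows_ss = (np.arange(n0)[:, None] + sub[None, :]).ravel()  # n0*ss
    cols_ss = (np.arange(n1)[:, None] + sub[None, :]).ravel()  # n1*ss

    hyper = [l for l in spec.lesions if isinstance(l, Hyperintensity)]

    vol = np.empty((n0, n1, nz))
    truth = np.empty((n0, n1, nz), dtype=np.uint8)

    def box_down(a: np.ndarray) -> np.ndarray:
        return a.reshape(n0, ss, n1, ss).mean(axis=(1, 3))

    for k in range(nz):
        dr = (rows_ss - c_row[k]) * sp[0]
        dc = (cols_ss - c_col[k]) * sp[1]
        d = np.sqrt(dr[:, None] ** 2 + dc[None, :] ** 2)  # mm
        cord = d <= radii[k]
        csf = (d > radii[k]) & (d <= radii[k] + thick[k])
        frac_cord = box_down(cord.astype(np.float64))
        frac_csf = box_down(csf.astype(np.float64))
        slab = (
            spec.background_intensity
            + (spec.cord_intensity - spec.background_intensity) * frac_cord
            + (spec.csf_intensity - spec.background_intensity) * frac_csf
        )
        for les in hyper:
            w = _taper(np.array([z_mm[k]]), les.center_mm, les.extent_mm)[0]
            if w <= 0:
                continue
            inside = (d <= min(les.radius_mm, radii[k])) & cord
            frac_les = box_down(inside.astype(np.float64))
            slab += w * (les.intensity - spec.cord_intensity) * frac_les
        vol[:, :, k] = slab
        truth[:, :, k] = frac_cord >= 0.5

    rng = np.random.default_rng(spec.seed)
    if spec.edge_blur_mm > 0:
        sigma_vox = tuple(spec.edge_blur_mm / s for s in sp)
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    if spec.bias_range is not None:
        lo, hi = spec.bias_range
        vol = vol * _bias_field(vol.shape, lo, hi, rng)
    if spec.noise_snr is not None:
        sigma = spec.cord_intensity / spec.noise_snr
        n1_, n2_ = rng.normal(0, sigma, vol.shape), rng.normal(0, sigma, vol.shape)
        vol = np.sqrt((vol + n1_) ** 2 + n2_**2)

    return PhantomInstance(
        volume=IntensityVolume(vol, sp),
        truth_mask=BinaryMask3D(truth, sp),
        truth_centerline=Centerline(c_row.copy(), c_col.copy()),
        truth_csa_mm2=np.pi * radii**2,
        spec=spec,
    )


def inject_failures(
    instance: PhantomInstance,
    fraction: float,
    seed: int = 0,
    displaced_fraction: float = 0.05,
    displacement_vox: float = 20.0,
) -> tuple[list[SliceSegmentation], list[int], list[int]]:
    """Corrupt per-slice segmentations to exercise the 3D repair step.

    Builds ok per-slice segmentations from the truth masks, then marks a
    random ``fraction`` of slices failed and shifts the masks of a disjoint
    random ``displaced_fraction`` of slices by ``displacement_vox`` voxels
    (default 20, i.e. above the 15-voxel discontinuity threshold) in a
    random in-plane direction.  Returns (slices, failed_idx, displaced_idx).
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    nz = instance.truth_mask.data.shape[2]
    n_fail = int(round(fraction * nz))
    n_disp = int(round(displaced_fraction * nz))
    perm = rng.permutation(nz)
    failed = sorted(int(i) for i in perm[:n_fail])
    displaced = sorted(int(i) for i in perm[n_fail : n_fail + n_disp])
    sp = instance.volume.in_plane_spacing

    out: list[SliceSegmentation] = []
    for k in range(nz):
        m = instance.truth_mask.data[:, :, k].astype(bool)
        if k in failed:
            out.append(SliceSegmentation(status="failed", failure_reason="injected"))
            continue
        if k in displaced:
            theta = rng.uniform(0, 2 * np.pi)
            shift = (
                int(round(displacement_vox * np.cos(theta))),
                int(round(displacement_vox * np.sin(theta))),
            )
            if np.hypot(*shift) <= displacement_vox * 0.75:  # guard tiny rounding
                shift = (int(round(displacement_vox)), 0)
            m = ndimage.shift(m.astype(float), shift, order=0, cval=0) > 0.5
        out.append(
            SliceSegmentation(
                status="ok",
                m_csf=np.zeros_like(m),
                m_f=m.copy(),
                m_sc=m,
                csa_mm2=compute_csa(m, sp),
            )
        )
    return out, failed, displaced
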