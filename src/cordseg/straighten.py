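"""Curved-to-straight reformatting of the cord along its centerline.

The volume is resampled in planes perpendicular to the smoothed centerline
(tricubic interpolation for intensities, nearest-neighbour for masks) with
the cord center mapped to the center of every output slice, so the
straightened cord is a vertical column centered in the field of view.
Output slices are placed at uniform arc length, making slice index
proportional to cord length — the property the later length standardization
relies on.

In-plane axes follow the centerline by parallel transport (rotation-
minimizing frames): unlike the Frenet frame, this is defined at zero
curvature and does not flip at inflections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .cord3d import Centerline, CordSegmentation
from .dtbm_core import AxialSlice
from .volume_io import BinaryMask3D, IntensityVolume

__all__ = [
    "StraightenedVolume",
    "frame_field",
    "straighten_volume",
    "select_c2_stack",
]


@dataclass
class StraightenedVolume:
    """A straightened cord volume: the cord center sits at the fixed
    in-plane position (``center_row``, ``center_col``) on every slice and
    slice k corresponds to arc length ``arc_length_mm[k]`` along the source
    centerline."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    center_row: float
    center_col: float
    arc_length_mm: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def axial_slice(self, k: int) -> np.ndarray:
        return self.data[:, :, k]

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing[0], self.spacing[1]


def _centerline_physical(
    centerline: Centerline, spacing: tuple[float, float, float]
) -> np.ndarray:
    """(n, 3) physical-mm points of the centerline (RL, AP, SI)."""
    if not centerline.present.all():
        raise ValueError("centerline must be complete (no absent slices)")
    n = centerline.n_slices
    pts = np.empty((n, 3))
    pts[:, 0] = centerline.rows * spacing[0]
    pts[:, 1] = centerline.cols * spacing[1]
    pts[:, 2] = np.arange(n) * spacing[2]
    return pts


def frame_field(
    centerline: Centerline, spacing: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frames along the centerline by parallel transport.

    Returns ``(points, tangents, u, v)``: physical points (mm), unit
    tangents from central differences, and the two in-plane axes obtained
    by transporting an initial normal with minimal rotation (no twist).
    """
    pts = _centerline_physical(centerline, spacing)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("centerline must contain at least 2 points")
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1)
    if (norms <= 1e-12).any():
        raise ValueError("degenerate tangent: zero-length centerline step")
    tangents /= norms[:, None]

    u = np.empty_like(tangents)
    v = np.empty_like(tangents)
    # initial in-plane axis: the RL direction projected off the tangent
    e = np.array([1.0, 0.0, 0.0])
    u0 = e - np.dot(e, tangents[0]) * tangents[0]
    if np.linalg.norm(u0) < 1e-8:
        e = np.array([0.0, 1.0, 0.0])
        u0 = e - np.dot(e, tangents[0]) * tangents[0]
    u[0] = u0 / np.linalg.norm(u0)
    v[0] = np.cross(tangents[0], u[0])
    for k in range(1, n):
        w = u[k - 1] - np.dot(u[k - 1], tangents[k]) * tangents[k]
        nw = np.linalg.norm(w)
        if nw < 1e-8:
            w = v[k - 1] - np.dot(v[k - 1], tangents[k]) * tangents[k]
            nw = np.linalg.norm(w)
        u[k] = w / nw
        v[k] = np.cross(tangents[k], u[k])
    return pts, tangents, u, v


def straighten_volume(
    vol: IntensityVolume,
    seg: CordSegmentation,
    out_plane_mm: Optional[float] = None,
    step_mm: Optional[float] = None,
) -> tuple[StraightenedVolume, BinaryMask3D]:
    """Resample volume and mask perpendicular to the centerline.

    Output slice k samples the plane at arc length ``k * step_mm`` along the
    smoothed centerline; the cord center maps to the in-plane grid center.
    Intensities are tricubically interpolated (clipped at 0), the mask by
    nearest neighbour.  Plane points outside the source field of view sample
    as 0 and are counted in a warning tally.
    """
    sp = vol.spacing
    if out_plane_mm is None:
        out_plane_mm = sp[0]
    if step_mm is None:
        step_mm = sp[2]
    pts, tangents, u, v = frame_field(seg.centerline, sp)

    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    n_out = int(np.ceil(total / step_mm)) + 1
    s_out = np.arange(n_out) * step_mm
    s_out = np.minimum(s_out, total)

    # interpolate centers and frames at the output arc lengths
    def interp_vec(field: np.ndarray) -> np.ndarray:
        out = np.empty((n_out, 3))
        for d in range(3):
            out[:, d] = np.interp(s_out, arc, field[:, d])
        return out

    centers = interp_vec(pts)
    uu = interp_vec(u)
    vv = interp_vec(v)
    uu /= np.linalg.norm(uu, axis=1)[:, None]
    # re-orthogonalize v against u after interpolation
    vv -= np.sum(vv * uu, axis=1)[:, None] * uu
    vv /= np.linalg.norm(vv, axis=1)[:, None]

    n0, n1 = vol.shape[0], vol.shape[1]
    ci, cj = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    ii = (np.arange(n0) - ci) * out_plane_mm
    jj = (np.arange(n1) - cj) * out_plane_mm
    gi, gj = np.meshgrid(ii, jj, indexing="ij")

    out_data = np.empty((n0, n1, n_out))
    out_mask = np.empty((n0, n1, n_out), dtype=np.uint8)
    n_outside = 0
    maskf = seg.mask.data
    shape = np.array(vol.shape, dtype=float)
    z_max = (vol.shape[2] - 1) * sp[2]
    t_lo, t_hi = tangents[0], tangents[-1]
    for k in range(n_out):
        phys = (
            centers[k][None, None, :]
            + gi[:, :, None] * uu[k][None, None, :]
            + gj[:, :, None] * vv[k][None, None, :]
        )
        # tilted end planes overhang the cropped SI range; the cord continues
        # there, so project overhanging points back along the end tangent to
        # the boundary plane (the tube extended straight past the crop)
        over_hi = phys[:, :, 2] > z_max
        if over_hi.any():
            d = (phys[:, :, 2][over_hi] - z_max) / t_hi[2]
            phys[over_hi] -= d[:, None] * t_hi[None, :]
        over_lo = phys[:, :, 2] < 0
        if over_lo.any():
            d = phys[:, :, 2][over_lo] / t_lo[2]
            phys[over_lo] -= d[:, None] * t_lo[None, :]
        voxf = phys / np.array(sp)[None, None, :]
        coords = np.stack([voxf[:, :, 0], voxf[:, :, 1], voxf[:, :, 2]])
        inside = np.all(
            (coords[:2] >= 0) & (coords[:2] <= (shape[:2] - 1)[:, None, None]), axis=0
        )
        n_outside += int((~inside).sum())
        sl = ndimage.map_coordinates(vol.data, coords, order=3, mode="constant", cval=0.0)
        out_data[:, :, k] = np.clip(sl, 0.0, None)
        out_mask[:, :, k] = ndimage.map_coordinates(
            maskf, coords, order=0, mode="constant", cval=0
        )
    if n_outside > 0:
        import warnings

        warnings.warn(
            f"{n_outside} straightened sample points fell outside the source FOV "
            "and were set to 0",
            stacklevel=2,
        )
    spacing_out = (out_plane_mm, out_plane_mm, step_mm)
    straight = StraightenedVolume(
        data=out_data,
        spacing=spacing_out,
        center_row=ci,
        center_col=cj,
        arc_length_mm=s_out,
    )
    return straight, BinaryMask3D(out_mask, spacing_out)


def select_c2_stack(
    straight: StraightenedVolume,
    disk_slice: int,
    slab_mm: float = 3.0,
    n_slabs: int = 5,
) -> list[AxialSlice]:
    """Average thin straightened slices into thick slabs above a landmark.

    The region superior to the (manually identified) C2/C3 disk is split
    into ``n_slabs`` contiguous slabs of ``slab_mm`` thickness; the most
    inferior slab is centered on ``disk_slice``.  Each returned slice is the
    voxelwise mean of its slab, emulating thick-slice cross-sectional
    acquisition at the C2 vertebral level.
    """
    step = straight.spacing[2]
    per_slab = max(1, int(round(slab_mm / step)))
    start = disk_slice - per_slab // 2
    stop = start + n_slabs * per_slab
    if start < 0 or stop > straight.n_slices:
        raise ValueError(
            "insufficient extent: the requested slabs do not fit "
            f"(slices {start}..{stop - 1} of {straight.n_slices})"
        )
    out = []
    sp = straight.in_plane_spacing
    for s in range(n_slabs):
        block = straight.data[:, :, start + s * per_slab : start + (s + 1) * per_slab]
        out.append(AxialSlice(block.mean(axis=2), sp))
    return out
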