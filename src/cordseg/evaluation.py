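"""Segmentation accuracy metrics: Dice similarity coefficient and relative
cross-sectional-area error against a reference (manual) segmentation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvaluationReport", "dice", "csa_error", "evaluate_segmentation"]


@dataclass
class EvaluationReport:
    """Per-slice and aggregate accuracy of a segmentation vs a reference.

    Slices where the reference is empty are excluded (n_slices counts only
    evaluated slices).  ``csa_error_pct`` is signed: negative means the
    evaluated segmentation underestimates the reference CSA.
    """

    dsc: np.ndarray
    csa_error_pct: np.ndarray
    mean_dsc: float
    mean_dsc_pct: float
    mean_csa_error_pct: float
    pooled_dsc: float
    n_slices: int


def dice(gt: np.ndarray, s: np.ndarray) -> float:
    """Dice similarity coefficient 2|GT n S| / (|GT| + |S|), in [0, 1]."""
    gt = np.asarray(gt).astype(bool)
    s = np.asarray(s).astype(bool)
    if gt.shape != s.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {s.shape}")
    denom = gt.sum() + s.sum()
    if denom == 0:
        raise ValueError("DSC undefined: both masks are empty")
    return 2.0 * np.count_nonzero(gt & s) / float(denom)


def csa_error(gt_csa: float, s_csa: float) -> float:
    """Relative CSA estimation error in percent: 100 (S - GT) / GT."""
    if gt_csa <= 0:
        raise ValueError("reference CSA must be positive")
    return 100.0 * (s_csa - gt_csa) / gt_csa


def evaluate_segmentation(
    gt: np.ndarray, s: np.ndarray, spacing: tuple[float, ...] | None = None
) -> EvaluationReport:
    """Slice-wise Dice and CSA error of ``s`` against reference ``gt``.

    Both masks are 3D with axial slices along the last axis.  Mean DSC is
    the average of per-slice DSC over slices where the reference is
    non-empty (matching per-subject aggregation of slice-wise tables);
    ``pooled_dsc`` additionally reports the single 3D overlap over all
    voxels.  Spacing only scales CSA, so the relative error is unaffected
    by its absence.
    """
    gt = np.asarray(gt).astype(bool)
    s = np.asarray(s).astype(bool)
    if gt.shape != s.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {s.shape}")
    px = 1.0 if spacing is None else float(spacing[0]) * float(spacing[1])
    dscs, errs = [], []
    for k in range(gt.shape[2]):
        g = gt[:, :, k]
        if not g.any():
            continue
        t = s[:, :, k]
        denom = g.sum() + t.sum()
        dscs.append(2.0 * np.count_nonzero(g & t) / float(denom))
        errs.append(csa_error(g.sum() * px, t.sum() * px))
    if not dscs:
        raise ValueError("reference mask is empty on every slice")
    dscs = np.asarray(dscs)
    errs = np.asarray(errs)
    return EvaluationReport(
        dsc=dscs,
        csa_error_pct=errs,
        mean_dsc=float(dscs.mean()),
        mean_dsc_pct=float(100.0 * dscs.mean()),
        mean_csa_error_pct=float(errs.mean()),
        pooled_dsc=dice(gt, s),
        n_slices=int(dscs.size),
    )
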