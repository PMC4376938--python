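"""Segment a realistic synthetic cord and score it against ground truth.

Generates a curved phantom (5 mm sinusoidal sagittal curvature) degraded
with edge blur, a 0.8-1.2x bias field and Rician noise at SNR 15, runs the
full double-threshold chain (per-slice S1-S6 plus the 3D centerline
correction S7), and prints the overlap with the exact truth mask.
"""

import numpy as np

import cordseg as cs

spec = cs.PhantomSpec(
    n_slices=210,
    curve_amplitude_mm=5.0,
    edge_blur_mm=0.3,
    noise_snr=15.0,
    bias_range=(0.8, 1.2),
    seed=7,
)
inst = cs.generate_phantom(spec)
print(f"phantom grid {inst.volume.shape} at {spec.spacing} mm")

slices = cs.segment_volume(inst.volume)
ok = sum(s.status == "ok" for s in slices)
print(f"per-slice segmentation: {ok}/{len(slices)} slices ok")

cord = cs.correct_segmentation(slices, spec.spacing)
print(f"3D correction: {cord.provenance.count('repaired')} slices repaired, "
      f"cord volume {cord.volume_mm3:.0f} mm^3")

rep = cs.evaluate_segmentation(inst.truth_mask.data, cord.mask.data, spec.spacing)
print(f"mean DSC vs truth: {rep.mean_dsc_pct:.2f}%  "
      f"(perfect overlap = 100%)")
print(f"mean CSA error: {rep.mean_csa_error_pct:+.2f}%  "
      f"(negative = the method underestimates the true cross-section)")
print(f"mean segmented CSA {np.nanmean(cord.csa_mm2):.2f} mm^2 "
      f"vs analytic truth {np.mean(inst.truth_csa_mm2):.2f} mm^2")
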