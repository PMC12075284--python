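"""Deformation metrics from an analytic displacement field.

Applies a composite motion (rigid rotation + simple shear) to a phantom,
computes Green-Lagrange strain, peak maximum principal strain (MPS) and
maximum resultant displacement (MRD), and summarises them the way cohort
deformation tables are reported.  The rigid part contributes no strain, so
the recovered MPS matches the closed-form shear value.
"""

import numpy as np

from brainmech import (
    MotionSpec, PhantomSpec, analytic_mps, deformation_summary,
    green_lagrange, make_anatomy, make_displacement, mps, mrd,
)

sub = make_anatomy(PhantomSpec(seed=4))
motion = MotionSpec(kind="composite", angle_rad=0.05, gamma=0.04, n_frames=5)
disp = make_displacement(sub.labels, motion)

mps_map = mps(green_lagrange(disp))
mrd_map = mrd(disp)
s = deformation_summary(mps_map, mrd_map, disp.valid)

print(f"MPS p50 = {s.mps_p50:.4f}, p95 = {s.mps_p95:.4f} "
      f"(ground-truth composite MPS = {analytic_mps(motion):.4f}; "
      "the rigid part alone would give 0)")
print(f"MRD p50 = {s.mrd_p50_mm:.2f} mm, p95 = {s.mrd_p95_mm:.2f} mm "
      "(displacement magnitude is dominated by the rigid rotation)")
for th, f in s.vf.items():
    print(f"volume fraction MPS > {th}: {f:.2f}")
interior = np.zeros(sub.labels.shape, bool)
interior[2:-2, 2:-2, 2:-2] = True
err = np.abs(mps_map.data[interior] - analytic_mps(motion)).max()
print(f"max interior deviation from the analytic MPS: {err:.2e} "
      "(finite strain is exactly rotation-invariant)")
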