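"""Track a needle tip with the conventional segmentation method (CSM).

Simulates one clean water insertion at acquisition scale (0.3 mm voxels),
then runs the three-stage pipeline — ROI search, fast-marching
segmentation, farthest-point tip extraction — on a few frames and compares
against the simulator's exact ground truth.
"""

import numpy as np

from needletrack import MediumSpec, NeedleSpec, TrajectorySpec, VolumeGrid, simulate_insertion
from needletrack.csm import CSMParams, detect_tip_csm

grid = VolumeGrid()  # 117 x 134 x 134 voxels at 0.3 mm
spec = TrajectorySpec(start_H=(-20.0, 0.0, -13.0))
record = simulate_insertion(grid, MediumSpec.water(), NeedleSpec(), spec, seed=17)

print("frame  detected tip (US, mm)        error (mm)")
for k in range(0, 41, 8):
    frame = record.frames[k]
    est = detect_tip_csm(frame.volume, CSMParams(), grid, direction=spec.direction())
    err = np.linalg.norm(est.position.values - frame.tip_US)
    x, y, z = est.position.values
    print(f"{k:5d}  ({x:6.2f}, {y:6.2f}, {z:6.2f})    {err:.3f}")

# Errors stay below two voxel pitches (0.6 mm) on clean frames, and the
# detected y coordinate tracks the 0.375 mm/frame advance of the needle.
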