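"""Estimate the hexapod -> ultrasound translation offset.

The rig assumes parallel coordinate axes, so calibration reduces to one
3-vector: the offset minimizing the mean discrepancy between needle tips
detected in US volumes and the commanded hexapod poses. With zero-mean
detection noise the least-squares estimate (the mean difference) is
unbiased; 10^4 pairs at sigma = 0.1 mm recover the offset to ~0.001 mm.
"""

import numpy as np

from needletrack.coords import Point3, estimate_translation

rng = np.random.default_rng(0)
true_offset = np.array([40.0, 32.0, 28.0])  # mm

tips_H = rng.uniform(-25, 0, size=(10_000, 3))
detected_US = tips_H + true_offset + rng.normal(0, 0.1, size=tips_H.shape)

pairs = [
    (Point3(d, frame="US"), Point3(t, frame="H"))
    for d, t in zip(detected_US, tips_H)
]
result = estimate_translation(pairs)

print("estimated offset (mm):", np.round(result.translation.offset, 4))
print("true offset      (mm):", true_offset)
print("residual RMS     (mm):", round(result.residual_rms_mm, 4))

# The residual RMS reflects only the injected detection noise; the offset
# itself is recovered to well under a hundredth of a millimetre per axis.
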