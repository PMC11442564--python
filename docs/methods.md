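# Methods

This note documents the models, numerical choices and open design decisions
behind `needletrack`, and what the synthetic experiments do and do not show.

## Problem setting and coordinate model

A six-degree-of-freedom hexapod robot drives a 2.15 mm trocar needle through
an imaging medium while a 16×16-element matrix transducer (0.3 mm element
pitch, 3 MHz, one system channel per element — 256 channels, so no
multiplexed acquisition) records B-mode volumes at 4 Hz. Volumes are
117×134×134 voxels at an isotropic 0.3 mm pitch; the depth axis covers a
5–40 mm field of view. Arrays are ordered (depth `z_US`, lateral `x_US`,
lateral `y_US`); millimetre points are (x, y, z) vectors.

The hexapod and ultrasound frames are modelled as parallel-axis frames
related by a pure translation `p_US = p_H + t`. The offset `t` is estimated
from pairs of detected and commanded tip positions; "minimizing the mean
error" is realized as least squares, whose closed form under a pure
translation is the componentwise mean difference (a geometric-median
variant, `method="least_absolute"`, is available for outlier-contaminated
detections but is not the default). Unit conversion between mm and pixel
coordinates divides by the single 0.3 mm pitch; pixel coordinates stay
continuous throughout and are rounded only at voxel lookup.

With zero tilt the needle advances along the negative `y_US` axis, and the
package uses the same convention in the hexapod frame (insertion along
`−y_H`). A rig in which insertion advances along `+y_H` while appearing as
`−y_US` motion cannot be expressed by a parallel-axes pure translation;
keeping one sign convention in both frames is the simplification consistent
with the transform model, and none of the detectors depends on it.

## Synthetic acquisition model

Real beamformed acquisitions from this probe are not publicly available, so
the simulator substitutes a descriptive appearance model on the exact
acquisition geometry:

- **Kinematics.** A trajectory is a straight line from a start pose:
  15 mm of travel at 1.5 mm/s (parallel protocol) or 1.0 mm/s (tilted),
  sampled at the 4 Hz volume rate with inclusive endpoints — 41 and 61
  poses respectively. Tilts `α_x`, `α_z` rotate the insertion axis about
  the hexapod x/z axes; consecutive tips differ by exactly
  `velocity/frame_rate` mm. The parallel protocol runs the 4×3 start grid
  `z_H ∈ {−8,−10,−13,−18}` × `x_H ∈ {−15,−20,−25}` mm; the tilted protocol
  runs a 3×3 grid (`z_H ∈ {−9,−13,−17}`, same `x_H` values, chosen here as
  a representative spread since only "varied positions" is specified) for
  each of the three angles `α_z = ±5°`, `α_x = −5°`. Inclusive-endpoint
  sampling makes all counts deterministic: 492 parallel frames, 1647
  tilted frames.
- **Background.** A smooth base level per medium, modulated by
  multiplicative Rayleigh speckle (unit mean, lightly correlated to give a
  ~voxel-scale grain) plus additive Gaussian sensor noise, quantized to
  8 bits. The liver preset adds random ellipsoidal inclusions and thin
  bright boundary sheets; water has no structures and weaker speckle. The
  presets are calibrated so that liver volumes have strictly higher
  background variance and scattered super-threshold (>128) clusters while
  water never crosses the detection threshold — the property that makes
  conventional detection degrade in tissue.
- **Needle.** A cylinder of the physical 2.15 mm diameter ending at the tip
  (flat end cap; the trocar bevel is below voxel scale and the tip
  *position* is the learning target), rendered at echo level 255, smoothed
  by a 0.3 mm Gaussian point spread, optionally followed by a
  comet-tail/reverberation artifact (attenuated replicas of the shaft at
  greater depth). Reverberation defaults to off: the clean configuration is
  the oracle for the conventional pipeline's accuracy contract, and the
  artifact strength is the controllable difficulty knob.
- **Determinism.** Every frame draws from a child stream of a single seed;
  identical (config, seed) reproduce datasets bit for bit.

The appearance model is noise on the *voxel lattice*: when a study is
scaled down by coarsening the pitch, speckle grain and smoothing lengths
follow the lattice, not physical wavelengths. Passing tests on synthetic
data therefore demonstrate correctness of the geometry, kinematics,
calibration and detector implementations, and achievable-in-principle
learning behavior — not performance on real probe data, whose artifacts
(side lobes, reverberation clutter, attenuation, beam-profile anisotropy)
are far richer.

## Conventional segmentation method

1. **ROI.** Median filter (default extents 3×3×25 voxels with the long
   axis along `y_US` — the elongated kernel preserves the elongated needle;
   the axis mapping is configurable), binarize above 128, connected
   components at 26-connectivity (needles at tilt cross voxel diagonals),
   keep the largest by voxel count (ties → brighter mean), center the ROI
   on its centroid: ±25 voxels in depth and `x_US`, never cropping `y_US`.
   Volumes on other intensity scales are min-max rescaled to 8 bits first.
2. **Segmentation.** On the *original* (unfiltered) ROI crop, a fast
   marching front starts at the maximum-intensity voxel (ties → closest to
   the ROI center) with speed `1/(1 + β·|I(v) − I(seed)|)` and the mask is
   all voxels with arrival time ≤ τ, restricted to the seed's component.
   The front solver is SimpleITK's first-order fast marching; its arrival
   times are exact along lattice axes and overestimate 3D-diagonal
   distances by up to ~13%, which the uniform-intensity contract test
   accounts for. β = 0.5 and τ = 160 (voxel units at 0.3 mm pitch) were
   fixed once against the bright-cylinder fixture (≥90% cylinder coverage,
   ≤5% background leakage); `CSMParams.for_pitch` rescales the voxel-unit
   defaults to other lattices.
3. **Tip.** The mask voxel with extreme projection onto the known insertion
   direction — the farthest point of the structure from its entry side.
   When a whole lattice plane ties (the flat end cap), the default
   tie-break takes the voxel nearest the tied set's centroid, which
   recovers the needle axis to sub-voxel accuracy; the alternative
   (farthest from the entry-face centroid) is available but systematically
   drifts to the cap rim, costing ~2 voxels of lateral accuracy, so it is
   not the default. Remaining ties resolve lexicographically; the whole
   pipeline is deterministic.

## Regression network

The learned detector is a DenseNet with all spatial operators in 3D:
stem convolution, dense blocks with BN–ReLU–(1×1 bottleneck)–3×3
convolutions and feature concatenation, compressing transitions with 2×
average pooling, and a BN–ReLU–global-average-pool–linear head onto exactly
3 outputs with no output nonlinearity. The default layout mirrors
DenseNet-121 (blocks 6/12/24/16, growth 32, bottleneck factor 4,
compression 0.5). Inputs are volumes cropped to 11.25–40 mm in depth and
7.5–32.85 mm laterally (index windows by round-half-up on mm/pitch —
32.85/0.3 = 109.5 is exactly half, so the rule is stated to make shapes
reproducible: the default crop is 96×85×85) and scaled to [0, 1]; no other
pre-processing, honoring the design intent of feeding raw low-resolution
volumes.

Training uses Adam, batch size 8, learning rate 1e-3 and an MSE loss on the
3-vector, with targets either in hexapod (`COS_H`) or ultrasound (`COS_US`)
coordinates, in mm or pixel units. The tested checkpoint is the epoch with
the lowest validation mean Euclidean tip error ("best performance" made
concrete). Internally targets are standardized per axis over the training
split (floor 1 unit on degenerate axes) because a zero-initialized head
cannot traverse tens of millimetres within desk-scale epochs at lr 1e-3;
predictions are de-standardized before any reporting and loss history is
reported in raw target units. Since standardization absorbs constant
offsets and global scales, `COS_H`- and `COS_US`-target training are
identical optimization problems on noiseless synthetic data, and px-target
predictions times the pitch equal mm-target predictions — both are verified
as tests.

The network runs on `needletrack.nn`, a compact CPU engine (im2col 3D
convolution, batch normalization, pooling, dense blocks, Adam) with manual
backpropagation, gradient-checked against finite differences in float64.
Everything is float32 in training and fully seeded; identical seeds give
identical weights, loss histories and checksums on one machine.

**Desk-scale profile.** The default study runs the reduced architecture
(blocks 2/2, growth 8, no bottleneck, 3³ stem) on the parallel protocol
simulated at 0.6 mm pitch and 2 Hz (21 frames per insertion), volumes
mean-pooled ×2 after cropping, 40 epochs — about three minutes on one CPU,
reaching ~1–1.5 mm held-out error. These problem sizes are the package's
default experimental scale; the full 800-epoch, full-resolution protocol
remains available via `ArchConfig()` + `TrainConfig.paper_protocol()`.

## Evaluation protocol

The error metric is the mean absolute translation error per hexapod axis,
`e_axis = (1/N) Σᵢ |l_i − p_i|`, with the overall `e` the arithmetic mean
of the three axis errors. The summation form is normalized by N — the
"mean" in the metric's name; sub-millimetre published magnitudes confirm
the 1/N. Dispersion defaults to the standard deviation over per-frame
absolute deviations; a fold-wise mode is provided since either aggregation
is defensible and the choice is not pinned down.

Parallel-protocol cross-validation fixes the test pair across all five
folds: the bottom-depth path (largest `z_US`) and a medium-depth path
(unique depth closest to the mid-range of depths, excluding the bottom),
labelled "bottom" and "upper" for the depth-stratified breakdown. Each
fold's validation pair is distinct from every other fold's and its two
paths share neither `z_H` nor `x_H` plane; the remaining eight insertions
train. The tilted scheme draws per fold and per angle one test and two
validation paths at random (seeded), training on the remaining six. The
tilted protocol is taken as 27 insertions (nine per angle); the 3/6/rest
split arithmetic is only satisfiable at that size.

## Known limitations

- The appearance model is descriptive, not physical: no wave propagation,
  beam profiles, side lobes or frequency-dependent attenuation. Absolute
  error magnitudes on synthetic data do not transfer to real probes.
- The conventional pipeline's fast-marching weights (functional form, β,
  τ) and seed rule are one concrete realization of a loosely specified
  method; they are validated only against the synthetic oracle.
- The hexapod-frame sign convention for insertion direction is a modelling
  simplification (see above).
- Ground-truth containment (the tip voxel lies inside the rendered bright
  needle) holds at pitches where the 2.15 mm needle spans voxels (0.3 and
  0.6 mm grids); on much coarser test lattices the needle is sub-voxel and
  the nearest voxel center can fall outside the cylinder.
- CPU training limits the default study to the reduced architecture and
  coarsened lattices; the full-resolution DenseNet-121 forward pass runs
  (seconds per volume) but its 800-epoch training protocol is impractical
  without a GPU.
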