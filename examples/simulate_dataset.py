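"""Generate a synthetic insertion dataset and inspect its ground truth.

Builds the parallel-insertion protocol (12 insertions on a 4 x 3 start
grid, 15 mm travel at 1.5 mm/s) on a coarsened 1.2 mm lattice so the demo
runs in seconds, then prints the per-frame manifest that a tracking study
trains and evaluates against.
"""

from needletrack import VolumeGrid, generate_dataset
from needletrack.phantom_sim import dataset_manifest

grid = VolumeGrid.from_fov(pitch=1.2)  # same 5-40 mm FOV, coarser voxels
records = generate_dataset("parallel", grid=grid, seed=0, frame_rate=1.0)

manifest = dataset_manifest(records, pitch=grid.pitch)
print(f"insertions: {len(records)}, frames: {len(manifest)}")
print(manifest[["insertion_id", "frame_idx", "tip_H_y_mm", "tip_US_y_mm", "tip_US_y_px"]].head(6))

# Each row ties one acquired volume to its exact needle-tip position in
# hexapod mm, ultrasound mm and continuous pixel units; the y coordinate
# decreases frame by frame because the needle advances along -y_US.
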