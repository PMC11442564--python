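"""Train the volumetric DenseNet to regress needle-tip positions.

Runs the desk-scale profile: the parallel protocol on a 0.9 mm lattice,
the reduced architecture (two dense blocks, growth 8), 15 epochs. The
network maps each cropped volume directly to the tip's hexapod-frame
millimetre position; held-out insertions test generalization to unseen
start positions. Takes a few minutes on one CPU.
"""

import numpy as np

from needletrack import VolumeGrid, generate_dataset
from needletrack.evaluate import make_cv_splits, translation_errors
from needletrack.phantom_sim import dataset_manifest
from needletrack.regressor import (
    ArchConfig,
    CropSpec,
    TrainConfig,
    build_arrays,
    build_model,
    train,
)

grid = VolumeGrid.from_fov(pitch=0.9)
records = generate_dataset("parallel", grid=grid, seed=11, frame_rate=2.0)
manifest = dataset_manifest(records, pitch=grid.pitch)
plan = make_cv_splits(manifest, "parallel", seed=0)
fold = plan.folds[0]

cfg = TrainConfig(epochs=15, downsample=2, learning_rate=3e-3, seed=3)
model = build_model(ArchConfig.reduced(), seed=3)
result = train(model, records, fold, cfg, grid=grid, crop=CropSpec())
print(result.history.tail(3).to_string(index=False))
print(f"selected checkpoint: epoch {result.best_epoch}, "
      f"validation mean tip error {result.best_val_error:.2f} mm")

x, y, groups = build_arrays(records, grid, cfg, crop=CropSpec())
held = np.isin(groups, fold["test"])
preds = np.concatenate([model.predict(x[held][i:i+16]) for i in range(0, held.sum(), 16)])
rep = translation_errors(y[held], preds)
print(f"held-out test insertions {fold['test']}: {rep}")

# The reported e is the across-axis mean absolute error on insertions the
# network never saw during training or checkpoint selection.
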