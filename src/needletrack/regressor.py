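"""Direct 3D needle-tip regression from a cropped low-resolution US volume.

A volumetric DenseNet maps one B-mode volume straight to the (x, y, z) tip
position — no needle segmentation, no manual annotation, no pre-processing
beyond cropping the field of view and scaling 8-bit intensities to [0, 1].
The default architecture mirrors the DenseNet-121 layout (dense blocks of
6/12/24/16 layers, growth 32, 1x1 bottlenecks, 0.5 transition compression)
with every spatial operator three-dimensional and a regression head: global
average pooling into a linear map onto 3 outputs, no output nonlinearity.

Training follows the acquisition-study protocol — Adam, mean squared error
on the 3-vector, batch size 8, learning rate 1e-3, checkpoint selection by
best validation performance — with a desk-scale profile (reduced dense
blocks, downsampled volumes, tens of epochs) as the default so the full
study runs on a single CPU; the 800-epoch full-resolution protocol remains
available through :meth:`TrainConfig.paper_protocol`.

Targets may be taken in the hexapod frame (COS_H, the precise robot poses)
or the ultrasound frame (COS_US), in millimetres or pixel units (mm divided
by the 0.3 mm pitch). Internally targets are standardized per axis over the
training split and predictions de-standardized before reporting; loss
history is reported in raw target units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import nn
from .coords import Point3
from .csm import TipEstimate
from .phantom_sim import InsertionRecord, VolumeGrid

__all__ = [
    "CropSpec",
    "ArchConfig",
    "TrainConfig",
    "DenseNet3D",
    "TrainResult",
    "crop_fov",
    "build_model",
    "build_arrays",
    "fit",
    "train",
    "predict_tip",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class CropSpec:
    """Millimetre crop window applied before the network sees a volume."""

    depth_mm: tuple[float, float] = (11.25, 40.0)
    lateral_x_mm: tuple[float, float] = (7.5, 32.85)
    lateral_y_mm: tuple[float, float] = (7.5, 32.85)


def _rhu(x: float) -> int:
    """Round half up (0.5 -> 1), the documented crop index rule."""
    return int(np.floor(x + 0.5))


def crop_fov(
    volume: np.ndarray, grid: VolumeGrid, spec: CropSpec = CropSpec()
) -> tuple[np.ndarray, VolumeGrid]:
    """Crop a volume to the spec's mm window; mm coordinates are preserved.

    Index windows are ``[round((lo - origin)/pitch), round((hi - origin)/pitch))``
    with round-half-up; the cropped grid keeps the new origins so a tip's mm
    position is unchanged by cropping.
    """
    p = grid.pitch
    ox, oy = grid.lateral_origin
    zw = (_rhu((spec.depth_mm[0] - grid.depth_min) / p), _rhu((spec.depth_mm[1] - grid.depth_min) / p))
    xw = (_rhu((spec.lateral_x_mm[0] - ox) / p), _rhu((spec.lateral_x_mm[1] - ox) / p))
    yw = (_rhu((spec.lateral_y_mm[0] - oy) / p), _rhu((spec.lateral_y_mm[1] - oy) / p))
    nz, nx, ny = grid.shape
    for (a, b), n, name in ((zw, nz, "depth"), (xw, nx, "x"), (yw, ny, "y")):
        if a < 0 or b > n or b <= a:
            raise ValueError(f"crop window {name}=({a},{b}) empty or outside the volume (0,{n})")
    cropped = volume[zw[0] : zw[1], xw[0] : xw[1], yw[0] : yw[1]]
    new_grid = VolumeGrid(
        shape=cropped.shape,
        pitch=p,
        depth_min=grid.depth_min + zw[0] * p,
        lateral_origin=(ox + xw[0] * p, oy + yw[0] * p),
    )
    return cropped, new_grid


@dataclass(frozen=True)
class ArchConfig:
    """Volumetric DenseNet layout. Defaults follow the DenseNet-121 layout."""

    block_layers: tuple[int, ...] = (6, 12, 24, 16)
    growth: int = 32
    init_features: int = 64
    bottleneck: bool = True
    bn_size: int = 4
    compression: float = 0.5
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool: bool = True
    n_outputs: int = 3

    def __post_init__(self) -> None:
        if self.n_outputs != 3:
            raise ValueError("the regression head predicts exactly a 3-vector")
        if not self.block_layers or any(n < 1 for n in self.block_layers):
            raise ValueError("block_layers must be non-empty positive counts")

    @property
    def n_dense_layers(self) -> int:
        return sum(self.block_layers)

    @property
    def min_input_size(self) -> int:
        """Smallest spatial extent the pooling cascade accepts."""
        f = self.stem_stride * (2 if self.stem_pool else 1) * 2 ** (len(self.block_layers) - 1)
        return f

    @classmethod
    def reduced(cls) -> "ArchConfig":
        """Desk-scale profile: two dense blocks, growth 8, no bottleneck."""
        return cls(
            block_layers=(2, 2),
            growth=8,
            init_features=8,
            bottleneck=False,
            stem_kernel=3,
            stem_stride=1,
            stem_pool=True,
        )


@dataclass
class TrainConfig:
    """Training protocol.

    The acquisition study trains for 800 epochs at batch size 8 and learning
    rate 1e-3 with Adam and an MSE loss; the desk default keeps optimizer,
    batch size and loss but runs far fewer epochs on downsampled volumes so
    a full cross-validated experiment fits on one CPU.
    """

    epochs: int = 40
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    target_frame: Literal["H", "US"] = "H"
    target_units: Literal["mm", "px"] = "mm"
    downsample: int = 2  # mean-pool factor applied after cropping
    pitch: float = 0.3  # mm per pixel for px targets

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.downsample) < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")

    @classmethod
    def paper_protocol(cls, **kw) -> "TrainConfig":
        return cls(epochs=800, batch_size=8, learning_rate=1e-3, downsample=1, **kw)


class DenseNet3D:
    """A 3D DenseNet regression network on the compact numpy engine."""

    def __init__(self, arch: ArchConfig, seed: int, dtype=np.float32) -> None:
        self.arch = arch
        self.seed = seed
        rng = np.random.default_rng(seed)
        ch = arch.init_features
        stem: list[nn.Layer] = [
            nn.Conv3d(1, ch, arch.stem_kernel, rng, stride=arch.stem_stride, dtype=dtype),
            nn.BatchNorm3d(ch, dtype=dtype),
            nn.ReLU(),
        ]
        if arch.stem_pool:
            stem.append(nn.MaxPool3d())
        body: list[nn.Layer] = []
        for i, n_layers in enumerate(arch.block_layers):
            block = nn.DenseBlock(ch, n_layers, arch.growth, rng, arch.bottleneck, arch.bn_size, dtype)
            body.append(block)
            ch = block.out_ch
            if i < len(arch.block_layers) - 1:
                out = max(1, int(np.floor(ch * arch.compression)))
                body.append(nn.Transition(ch, out, rng, dtype))
                ch = out
        head = [nn.BatchNorm3d(ch, dtype=dtype), nn.ReLU(), nn.GlobalAvgPool3d(), nn.Linear(ch, arch.n_outputs, rng, dtype)]
        self.net = nn.Sequential(stem + body + head)
        # target normalization fitted during training (identity until then)
        self.target_center = np.zeros(3)
        self.target_scale = np.ones(3)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, D, H, W) input, got {x.shape}")
        m = self.arch.min_input_size
        if min(x.shape[2:]) < m:
            raise ValueError(
                f"input spatial size {x.shape[2:]} too small for the pooling cascade; "
                f"minimum is {m} voxels per axis"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def predict_normalized(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """De-standardized predictions in raw target units."""
        return self.predict_normalized(x) * self.target_scale + self.target_center

    # --- state handling -------------------------------------------------
    def _bn_layers(self) -> list[nn.BatchNorm3d]:
        out = []

        def walk(layer):
            if isinstance(layer, nn.BatchNorm3d):
                out.append(layer)
            for attr in ("layers", "net"):
                sub = getattr(layer, attr, None)
                if isinstance(sub, list):
                    for s in sub:
                        walk(s)
                elif sub is not None:
                    walk(sub)

        walk(self.net)
        return out

    def get_state(self) -> dict:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        state["target_center"] = self.target_center.copy()
        state["target_scale"] = self.target_scale.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"bn_{i}_mean"]
            bn.running_var[...] = state[f"bn_{i}_var"]
        self.target_center = np.asarray(state["target_center"], dtype=float)
        self.target_scale = np.asarray(state["target_scale"], dtype=float)

    def checksum(self) -> str:
        return nn.parameter_checksum(self.params())


def build_model(arch: ArchConfig = ArchConfig(), seed: int = 0, dtype=np.float32) -> DenseNet3D:
    """Construct a seeded 3D DenseNet; identical seeds give identical weights."""
    return DenseNet3D(arch, seed, dtype=dtype)


def downsample_volume(vol: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool by an integer factor (trailing voxels beyond a multiple dropped)."""
    if factor == 1:
        return np.asarray(vol, dtype=np.float32)
    d, h, w = (s // factor for s in vol.shape)
    v = np.asarray(vol[: d * factor, : h * factor, : w * factor], dtype=np.float32)
    return v.reshape(d, factor, h, factor, w, factor).mean(axis=(1, 3, 5))


def build_arrays(
    records: Sequence[InsertionRecord],
    grid: VolumeGrid,
    cfg: TrainConfig,
    crop: CropSpec | None = None,
    frame_stride: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn insertion records into network inputs and targets.

    Returns ``(X, Y, groups)``: X is (N, 1, D, H, W) float32 in [0, 1]; Y is
    (N, 3) in the config's frame and units; groups holds the insertion id of
    each frame (for grouped splitting).
    """
    xs, ys, gs = [], [], []
    for rec in records:
        for f in rec.frames[::frame_stride]:
            vol = f.volume
            if crop is not None:
                vol, _ = crop_fov(vol, grid, crop)
            v = downsample_volume(vol, cfg.downsample) / 255.0
            xs.append(v[None])
            tip = f.tip_H if cfg.target_frame == "H" else f.tip_US
            if cfg.target_units == "px":
                tip = tip / cfg.pitch
            ys.append(tip)
            gs.append(rec.id)
    return np.stack(xs).astype(np.float32), np.asarray(ys, dtype=float), np.asarray(gs)


@dataclass
class TrainResult:
    """Fitted model plus its training history and selected checkpoint."""

    model: DenseNet3D
    history: "object"  # pandas DataFrame: epoch, train_mse, val_mse, val_mean_err
    best_epoch: int
    best_val_error: float
    config: TrainConfig = field(default_factory=TrainConfig)


def fit(
    model: DenseNet3D,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    cfg: TrainConfig = TrainConfig(),
    scale_floor: float = 1.0,
) -> TrainResult:
    """Train with Adam/MSE; select the checkpoint with the lowest validation
    mean Euclidean error. All randomness is derived from ``cfg.seed``.

    Losses in the returned history are in raw target units (mm or px).
    """
    import pandas as pd

    if len(x_train) == 0 or (x_val is not None and len(x_val) == 0):
        raise ValueError("empty train or validation partition")
    rng = np.random.default_rng(cfg.seed)
    center = y_train.mean(axis=0)
    scale = np.maximum(y_train.std(axis=0), scale_floor)
    model.target_center, model.target_scale = center, scale
    yn_train = (y_train - center) / scale
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    n = len(x_train)
    rows = []
    best = (np.inf, None, -1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot_raw, steps = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x_train[idx]
            yb = yn_train[idx]
            pred = model.forward(xb, train=True)
            loss, dpred = nn.mse_loss(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {steps}: {loss}"
                )
            opt.zero_grad()
            model.backward(dpred)
            opt.step()
            raw_mse = float(np.mean(((pred - yb) * scale) ** 2))
            tot_raw += raw_mse * len(idx)
            steps += 1
        train_mse = tot_raw / n
        row = {"epoch": epoch, "train_mse": train_mse}
        if x_val is not None:
            pv = _predict_batched(model, x_val)
            resid = pv - y_val
            row["val_mse"] = float(np.mean(resid**2))
            row["val_mean_err"] = float(np.mean(np.linalg.norm(resid, axis=1)))
            if row["val_mean_err"] < best[0]:
                best = (row["val_mean_err"], model.get_state(), epoch)
        rows.append(row)
    if best[1] is not None:
        model.set_state(best[1])
        best_epoch, best_err = best[2], best[0]
    else:
        best_epoch, best_err = cfg.epochs - 1, float("nan")
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_error=best_err,
        config=cfg,
    )


def _predict_batched(model: DenseNet3D, x: np.ndarray, batch: int = 16) -> np.ndarray:
    return np.concatenate([model.predict(x[i : i + batch]) for i in range(0, len(x), batch)])


def train(
    model: DenseNet3D,
    records: Sequence[InsertionRecord],
    split: dict,
    cfg: TrainConfig = TrainConfig(),
    grid: VolumeGrid | None = None,
    crop: CropSpec | None = None,
    frame_stride: int = 1,
) -> TrainResult:
    """Train on insertion records using an insertion-level split.

    ``split`` maps ``"train"`` and ``"val"`` to disjoint insertion-id sets;
    targets are taken from the records in the config's frame and units.
    """
    grid = grid or VolumeGrid()
    train_ids, val_ids = set(split["train"]), set(split.get("val", ()))
    if train_ids & val_ids:
        raise ValueError("train and validation insertion sets overlap")
    x, y, groups = build_arrays(records, grid, cfg, crop, frame_stride)
    tr = np.isin(groups, list(train_ids))
    va = np.isin(groups, list(val_ids))
    if not tr.any() or (val_ids and not va.any()):
        raise ValueError("empty train or validation partition after splitting")
    return fit(
        model,
        x[tr],
        y[tr],
        x[va] if val_ids else None,
        y[va] if val_ids else None,
        cfg,
    )


def predict_tip(
    model: DenseNet3D,
    volume: np.ndarray,
    grid: VolumeGrid,
    cfg: TrainConfig,
    crop: CropSpec | None = None,
    frame_index: int | None = None,
) -> TipEstimate:
    """Single-forward-pass tip prediction for one volume.

    The volume must be on the training grid and is cropped/downsampled with
    the training settings; the estimate is in the config's frame and units
    (px estimates convert to mm by multiplying with the pitch).
    """
    vol = volume
    if crop is not None:
        vol, _ = crop_fov(vol, grid, crop)
    v = downsample_volume(vol, cfg.downsample) / 255.0
    pred = model.predict(v[None, None].astype(np.float32))[0]
    return TipEstimate(
        position=Point3(pred, frame=cfg.target_frame, units=cfg.target_units),
        method="densenet",
        frame_index=frame_index,
        diagnostics={"downsample": cfg.downsample},
    )


def save_checkpoint(path: str | Path, result: TrainResult, crop: CropSpec | None = None) -> None:
    """Single-file checkpoint embedding weights, configs and the seed."""
    path = Path(path)
    meta = {
        "arch": asdict(result.model.arch),
        "train": asdict(result.config),
        "crop": asdict(crop) if crop is not None else None,
        "seed": result.model.seed,
        "best_epoch": result.best_epoch,
        "best_val_error": result.best_val_error,
    }
    np.savez_compressed(path, __meta__=json.dumps(meta), **result.model.get_state())


def load_checkpoint(path: str | Path) -> tuple[DenseNet3D, dict]:
    """Rebuild a model from a checkpoint; returns (model, metadata)."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arch_d = dict(meta["arch"])
        arch_d["block_layers"] = tuple(arch_d["block_layers"])
        model = DenseNet3D(ArchConfig(**arch_d), seed=meta["seed"])
        model.set_state({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta
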