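"""End-to-end experiment runner: simulate, detect, evaluate.

A :class:`RunConfig` fully describes one experiment — the voxel grid, the
medium, the insertion protocol, the detection method(s) and the evaluation
scheme — and is serializable to YAML, so a run is reproducible from its
archived config and seed alone. Every output artifact carries the config
hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .coords import RigidTranslation
from .csm import CSMParams, NoStructureError, detect_tip_csm
from .evaluate import depth_breakdown, make_cv_splits, summarize
from .phantom_sim import (
    DEFAULT_TRANSFORM,
    MediumSpec,
    NeedleSpec,
    VolumeGrid,
    dataset_manifest,
    generate_dataset,
)
from .regressor import ArchConfig, CropSpec, TrainConfig, build_model, predict_tip, train

logger = logging.getLogger("needletrack")

__all__ = ["RunConfig", "ExperimentReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable description of one experiment run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    protocol: Literal["parallel", "tilted"] = "parallel"
    medium: Literal["water", "liver"] = "water"
    methods: tuple[str, ...] = ("csm",)
    # geometry; pitch > 0.3 scales the whole study down for desk-scale runs
    pitch: float = 0.3
    frame_rate: float = 4.0
    transform_offset: tuple[float, float, float] = (40.0, 32.0, 28.0)
    needle_reverb: float = 0.0
    # csm
    csm: dict = field(default_factory=dict)
    # regressor
    arch_profile: Literal["reduced", "full"] = "reduced"
    train: dict = field(default_factory=dict)
    use_crop: bool = True
    n_folds: int = 1  # folds actually trained (split plan always has 5)
    frame_stride: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.transform_offset = tuple(float(v) for v in self.transform_offset)
        self.methods = tuple(self.methods)
        known = {"csm", "densenet"}
        bad = set(self.methods) - known
        if bad:
            raise PipelineError("config", f"unknown method name(s) {sorted(bad)}; known: {sorted(known)}")
        if self.protocol not in ("parallel", "tilted"):
            raise PipelineError("config", f"unknown protocol {self.protocol!r}")
        if self.medium not in ("water", "liver"):
            raise PipelineError("config", f"unknown medium {self.medium!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["methods"] = tuple(raw.get("methods", ("csm",)))
        raw["transform_offset"] = tuple(raw.get("transform_offset", DEFAULT_TRANSFORM.offset))
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Outputs of one pipeline run."""

    config: RunConfig
    manifest: pd.DataFrame
    results: pd.DataFrame  # one row per evaluated frame
    summary: pd.DataFrame
    depth_summary: pd.DataFrame | None
    out_dir: Path


def _scaled_geometry(cfg: RunConfig) -> tuple[VolumeGrid, CropSpec | None]:
    grid = VolumeGrid.from_fov(pitch=cfg.pitch)
    crop = CropSpec() if cfg.use_crop else None
    return grid, crop


def _evaluate_csm(cfg, grid, records, rows) -> None:
    params = CSMParams.for_pitch(cfg.pitch, **cfg.csm)
    for rec in records:
        d = rec.trajectory.direction()
        for k, f in enumerate(rec.frames[:: cfg.frame_stride]):
            try:
                est = detect_tip_csm(f.volume, params, grid, direction=d, frame_index=k)
            except NoStructureError:
                logger.warning("no structure in %s frame %d", rec.id, k)
                continue
            pred_H = est.position.values - np.asarray(cfg.transform_offset)
            rows.append(
                {
                    "method": "csm", "target": "COS_H", "medium": cfg.medium,
                    "insertion_id": rec.id, "frame_idx": k, "fold": 0,
                    "l_x": f.tip_H[0], "l_y": f.tip_H[1], "l_z": f.tip_H[2],
                    "p_x": pred_H[0], "p_y": pred_H[1], "p_z": pred_H[2],
                }
            )


def _evaluate_densenet(cfg, grid, crop, records, manifest, rows) -> None:
    plan = make_cv_splits(manifest, cfg.protocol, seed=cfg.seed)
    arch = ArchConfig.reduced() if cfg.arch_profile == "reduced" else ArchConfig()
    tcfg = TrainConfig(**{"seed": cfg.seed, **cfg.train})
    by_id = {r.id: r for r in records}
    for fold_idx, fold in enumerate(plan.folds[: cfg.n_folds]):
        model = build_model(arch, seed=cfg.seed + fold_idx)
        result = train(
            model, records, fold, tcfg, grid=grid, crop=crop,
            frame_stride=cfg.frame_stride,
        )
        logger.info(
            "fold %d: best epoch %d, val err %.3f", fold_idx, result.best_epoch,
            result.best_val_error,
        )
        for tid in fold["test"]:
            rec = by_id[tid]
            for k, f in enumerate(rec.frames[:: cfg.frame_stride]):
                est = predict_tip(model, f.volume, grid, tcfg, crop=crop, frame_index=k)
                pred = est.position.values
                if tcfg.target_units == "px":
                    pred = pred * tcfg.pitch
                label = f.tip_H if tcfg.target_frame == "H" else f.tip_US
                rows.append(
                    {
                        "method": "densenet", "target": f"COS_{tcfg.target_frame}",
                        "medium": cfg.medium, "insertion_id": rec.id,
                        "frame_idx": k, "fold": fold_idx,
                        "depth_label": plan.depth_labels.get(tid),
                        "l_x": label[0], "l_y": label[1], "l_z": label[2],
                        "p_x": pred[0], "p_y": pred[1], "p_z": pred[2],
                    }
                )


def run_pipeline(config: RunConfig) -> ExperimentReport:
    """Simulate the configured protocol, run the detector(s), evaluate.

    Emits manifest, per-frame predictions, summary tables, the config
    snapshot and a log file into ``config.out_dir``. Any stage error is
    re-raised as :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    chash = config.config_hash()
    logger.info("run config hash %s", chash)
    try:
        grid, crop = _scaled_geometry(config)
        medium = MediumSpec.water() if config.medium == "water" else MediumSpec.liver()
        needle = NeedleSpec(reverb_strength=config.needle_reverb)
        try:
            records = generate_dataset(
                config.protocol, grid=grid, medium=medium, needle=needle,
                transform=RigidTranslation(np.asarray(config.transform_offset)),
                seed=config.seed, frame_rate=config.frame_rate,
            )
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        manifest = dataset_manifest(records, pitch=grid.pitch)
        manifest.insert(0, "config_hash", chash)
        manifest.to_csv(out / "manifest.csv", index=False)

        rows: list[dict] = []
        if "csm" in config.methods:
            try:
                _evaluate_csm(config, grid, records, rows)
            except Exception as exc:
                raise PipelineError("detect-csm", str(exc)) from exc
        if "densenet" in config.methods:
            try:
                _evaluate_densenet(config, grid, crop, records, manifest, rows)
            except Exception as exc:
                raise PipelineError("train-predict", str(exc)) from exc

        results = pd.DataFrame(rows)
        if len(results) == 0:
            raise PipelineError("evaluate", "no predictions were produced")
        results.insert(0, "config_hash", chash)
        results.to_csv(out / "predictions.csv", index=False)
        try:
            summary = summarize(results)
            summary.insert(0, "config_hash", chash)
            depth = None
            if "depth_label" in results.columns and results["depth_label"].notna().any():
                depth = depth_breakdown(results[results["depth_label"].notna()])
        except Exception as exc:
            raise PipelineError("evaluate", str(exc)) from exc
        summary.to_csv(out / "summary.csv", index=False)
        if depth is not None:
            depth.to_csv(out / "summary_by_depth.csv", index=False)
        config.to_yaml(out / "config.yaml")
        logger.info("summary:\n%s", summary.to_string())
        return ExperimentReport(
            config=config, manifest=manifest, results=results,
            summary=summary, depth_summary=depth, out_dir=out,
        )
    finally:
        logger.removeHandler(fh)
        fh.close()
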