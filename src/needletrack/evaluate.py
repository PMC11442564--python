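"""Tracking-error metrics, cross-validation split schemes and result tables.

The study's headline metric is the mean absolute translation error

    e = (1/N) * sum_i |l_i - p_i|

computed per hexapod axis over N volumes (l_i the label, p_i the prediction)
and summarized as the arithmetic mean of the three per-axis errors. Under
the rig's parallel-axes assumption the numbers are identical in US axes.

Two fivefold split schemes mirror the acquisition protocols:

``parallel``
    twelve insertions on a 4 (height) x 3 (horizontal) start grid. The test
    pair — one medium-depth and one bottom-depth path — is fixed across all
    five folds; each fold draws a fresh validation pair whose two paths share
    neither a z_H plane nor an x_H plane; the remainder trains.
``tilted``
    27 insertions, nine per tilt angle. Each fold randomly assigns, per
    angle, one test path and two validation paths; the remainder trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ErrorReport",
    "SplitPlan",
    "SplitConstraintError",
    "translation_errors",
    "combine_axis_errors",
    "make_cv_splits",
    "summarize",
    "depth_breakdown",
]

AXES = ("x", "y", "z")


class SplitConstraintError(ValueError):
    """The manifest cannot satisfy the split scheme's quotas or constraints."""


@dataclass(frozen=True)
class ErrorReport:
    """Overall and per-axis mean absolute errors with dispersion (mm)."""

    e: float
    e_x: float
    e_y: float
    e_z: float
    std: float
    std_x: float
    std_y: float
    std_z: float
    n: int

    def to_dict(self) -> dict:
        return {
            "e": self.e, "e_x": self.e_x, "e_y": self.e_y, "e_z": self.e_z,
            "std": self.std, "std_x": self.std_x, "std_y": self.std_y,
            "std_z": self.std_z, "n": self.n,
        }

    def __str__(self) -> str:
        return (
            f"e={self.e:.2f}±{self.std:.2f}  "
            f"e_x={self.e_x:.2f}±{self.std_x:.2f}  "
            f"e_y={self.e_y:.2f}±{self.std_y:.2f}  "
            f"e_z={self.e_z:.2f}±{self.std_z:.2f}  (N={self.n})"
        )


def translation_errors(labels: np.ndarray, preds: np.ndarray) -> ErrorReport:
    """Mean absolute translation error of predictions against labels.

    ``labels`` and ``preds`` are (N, 3) arrays in mm. Per-axis errors are
    mean absolute deviations; the overall ``e`` is their arithmetic mean
    (equivalently the mean over frames of the per-frame across-axis mean
    absolute deviation). Dispersion is the standard deviation of the
    per-frame absolute deviations.
    """
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    preds = np.atleast_2d(np.asarray(preds, dtype=float))
    if labels.shape != preds.shape or labels.ndim != 2 or labels.shape[1] != 3:
        raise ValueError(f"labels {labels.shape} and preds {preds.shape} must both be (N, 3)")
    if len(labels) == 0:
        raise ValueError("need at least one (label, prediction) pair")
    absdev = np.abs(labels - preds)  # (N, 3)
    per_axis = absdev.mean(axis=0)
    per_frame = absdev.mean(axis=1)
    return ErrorReport(
        e=float(per_frame.mean()),
        e_x=float(per_axis[0]), e_y=float(per_axis[1]), e_z=float(per_axis[2]),
        std=float(per_frame.std()),
        std_x=float(absdev[:, 0].std()), std_y=float(absdev[:, 1].std()),
        std_z=float(absdev[:, 2].std()),
        n=len(labels),
    )


def combine_axis_errors(e_x: float, e_y: float, e_z: float) -> float:
    """Across-axis aggregation used in the summary tables: the arithmetic mean."""
    return (e_x + e_y + e_z) / 3.0


@dataclass
class SplitPlan:
    """Per-fold train/validation/test insertion-id assignment."""

    scheme: Literal["parallel", "tilted"]
    folds: list[dict]  # each: {"train": [...], "val": [...], "test": [...]}
    depth_labels: dict = field(default_factory=dict)  # test id -> "upper" | "bottom"
    seed: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "depth_labels": self.depth_labels,
            "folds": [
                {k: sorted(v) for k, v in fold.items()} for fold in self.folds
            ],
        }


def _insertion_table(manifest: pd.DataFrame) -> pd.DataFrame:
    req = {"insertion_id", "start_x_H", "start_z_H", "alpha_x", "alpha_z"}
    missing = req - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    cols = ["insertion_id", "start_x_H", "start_z_H", "alpha_x", "alpha_z"]
    if "tip_US_z_mm" in manifest.columns:
        ins = manifest.groupby("insertion_id", as_index=False).agg(
            start_x_H=("start_x_H", "first"), start_z_H=("start_z_H", "first"),
            alpha_x=("alpha_x", "first"), alpha_z=("alpha_z", "first"),
            depth_US=("tip_US_z_mm", "mean"),
        )
    else:
        ins = manifest[cols].drop_duplicates("insertion_id").copy()
        ins["depth_US"] = -ins["start_z_H"]  # deeper hexapod height = deeper in US
    return ins.sort_values("insertion_id").reset_index(drop=True)


def _parallel_splits(ins: pd.DataFrame, seed: int, n_folds: int) -> SplitPlan:
    if len(ins) != 12:
        raise SplitConstraintError(
            f"parallel scheme expects 12 insertions, manifest has {len(ins)}"
        )
    depths = np.sort(ins["depth_US"].unique())
    if len(depths) < 3:
        raise SplitConstraintError("parallel scheme needs at least 3 distinct depths")
    bottom_depth = depths[-1]
    inner = depths[:-1]
    medium_depth = inner[np.argmin(np.abs(inner - (depths[0] + depths[-1]) / 2.0))]
    bottom_rows = ins[ins["depth_US"] == bottom_depth]
    medium_rows = ins[ins["depth_US"] == medium_depth]
    medium_id = medium_rows.iloc[0]["insertion_id"]
    med_x = medium_rows.iloc[0]["start_x_H"]
    other_x = bottom_rows[bottom_rows["start_x_H"] != med_x]
    bottom_id = (other_x if len(other_x) else bottom_rows).iloc[0]["insertion_id"]
    test = [medium_id, bottom_id]
    depth_labels = {medium_id: "upper", bottom_id: "bottom"}

    pool = ins[~ins["insertion_id"].isin(test)]
    by_id = pool.set_index("insertion_id")
    pairs = [
        (a, b)
        for a, b in combinations(sorted(by_id.index), 2)
        if by_id.loc[a, "start_z_H"] != by_id.loc[b, "start_z_H"]
        and by_id.loc[a, "start_x_H"] != by_id.loc[b, "start_x_H"]
    ]
    if len(pairs) < n_folds:
        raise SplitConstraintError(
            "cannot draw enough validation pairs differing in both z_H and x_H"
        )
    rng = np.random.default_rng(seed)
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=n_folds, replace=False)]
    folds = []
    for val in chosen:
        train = sorted(set(by_id.index) - set(val))
        folds.append({"train": train, "val": sorted(val), "test": sorted(test)})
    return SplitPlan(scheme="parallel", folds=folds, depth_labels=depth_labels, seed=seed)


def _tilted_splits(ins: pd.DataFrame, seed: int, n_folds: int) -> SplitPlan:
    angles = ins.groupby(["alpha_x", "alpha_z"])["insertion_id"].apply(list)
    if len(angles) != 3 or any(len(v) < 9 for v in angles):
        raise SplitConstraintError(
            "tilted scheme expects 3 tilt angles with 9 insertions each; got "
            + ", ".join(f"{k}: {len(v)}" for k, v in angles.items())
        )
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        test, val, train = [], [], []
        for ids in angles:
            ids = sorted(ids)
            perm = rng.permutation(len(ids))
            test.append(ids[perm[0]])
            val += [ids[perm[1]], ids[perm[2]]]
            train += [ids[i] for i in perm[3:]]
        folds.append({"train": sorted(train), "val": sorted(val), "test": sorted(test)})
    return SplitPlan(scheme="tilted", folds=folds, seed=seed)


def make_cv_splits(
    manifest: pd.DataFrame,
    scheme: Literal["parallel", "tilted"],
    seed: int = 0,
    n_folds: int = 5,
) -> SplitPlan:
    """Build the fivefold split plan for a dataset manifest.

    Raises :class:`SplitConstraintError` naming the violated constraint when
    the manifest's insertion structure cannot satisfy the scheme.
    """
    ins = _insertion_table(manifest)
    if scheme == "parallel":
        return _parallel_splits(ins, seed, n_folds)
    if scheme == "tilted":
        return _tilted_splits(ins, seed, n_folds)
    raise ValueError(f"unknown split scheme {scheme!r}")


_LABEL_COLS = ["l_x", "l_y", "l_z"]
_PRED_COLS = ["p_x", "p_y", "p_z"]


def _require_results(results: pd.DataFrame) -> None:
    if len(results) == 0:
        raise ValueError("empty results")
    missing = set(_LABEL_COLS + _PRED_COLS) - set(results.columns)
    if missing:
        raise ValueError(f"results lack columns {sorted(missing)}")


def summarize(
    results: pd.DataFrame,
    by: Sequence[str] = ("method", "target", "medium"),
    dispersion: Literal["frames", "folds"] = "frames",
) -> pd.DataFrame:
    """Summary table: mean ± std of e and per-axis errors per group.

    ``results`` holds one row per evaluated frame with label columns
    ``l_x,l_y,l_z``, prediction columns ``p_x,p_y,p_z`` and the grouping
    columns. ``dispersion="frames"`` spreads over per-frame absolute errors;
    ``"folds"`` over per-fold means (requires a ``fold`` column). The table
    is order-invariant in the input rows.
    """
    _require_results(results)
    by = [c for c in by if c in results.columns]
    groups = results.groupby(list(by)) if by else [((), results)]
    rows = []
    for key, grp in groups:
        key = key if isinstance(key, tuple) else (key,)
        labels = grp[_LABEL_COLS].to_numpy()
        preds = grp[_PRED_COLS].to_numpy()
        rep = translation_errors(labels, preds)
        row = dict(zip(by, key))
        if dispersion == "folds":
            if "fold" not in grp.columns:
                raise ValueError('dispersion="folds" needs a "fold" column')
            per_fold = [
                translation_errors(g[_LABEL_COLS].to_numpy(), g[_PRED_COLS].to_numpy())
                for _, g in grp.groupby("fold")
            ]
            row.update(
                e=float(np.mean([r.e for r in per_fold])),
                std=float(np.std([r.e for r in per_fold])),
                e_x=float(np.mean([r.e_x for r in per_fold])),
                std_x=float(np.std([r.e_x for r in per_fold])),
                e_y=float(np.mean([r.e_y for r in per_fold])),
                std_y=float(np.std([r.e_y for r in per_fold])),
                e_z=float(np.mean([r.e_z for r in per_fold])),
                std_z=float(np.std([r.e_z for r in per_fold])),
                n=rep.n,
            )
        else:
            row.update(rep.to_dict())
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(by).reset_index(drop=True) if by else out


def depth_breakdown(results: pd.DataFrame, by: Sequence[str] = ("method", "medium")) -> pd.DataFrame:
    """Secondary table split by test-path depth (upper vs bottom insertion)."""
    _require_results(results)
    if "depth_label" not in results.columns:
        raise ValueError("results lack a 'depth_label' column (upper/bottom)")
    return summarize(results, by=list(by) + ["depth_label"])


def plot_depth_boxplot(results: pd.DataFrame, path: str) -> None:
    """Boxplot of per-frame errors, upper vs bottom test path, per axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _require_results(results)
    absdev = np.abs(
        results[_LABEL_COLS].to_numpy() - results[_PRED_COLS].to_numpy()
    )
    fig, axes = plt.subplots(1, 3, figsize=(9, 3), sharey=True)
    for k, (ax, name) in enumerate(zip(axes, ("x_H", "y_H", "z_H"))):
        data = [
            absdev[results["depth_label"].to_numpy() == lab, k]
            for lab in ("upper", "bottom")
        ]
        ax.boxplot(data, tick_labels=["upper", "bottom"])
        ax.set_title(f"error along {name}")
        ax.set_ylabel("abs error (mm)" if k == 0 else "")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
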