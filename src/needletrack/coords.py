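"""Coordinate frames, unit conversion and hexapod->ultrasound calibration.

Two right-handed frames are used throughout the package:

``H``
    The hexapod (robot) frame. Needle-tip ground truth is recorded here in
    millimetres, with an axial repeatability far below the voxel pitch, so
    these poses serve as training and evaluation labels.
``US``
    The ultrasound volume frame. Axes are assumed parallel to the hexapod
    axes, so the rigid mapping between the two frames reduces to a pure
    translation offset (estimated once per rig from detected tip positions).

Points carry explicit frame and unit tags (:class:`Point3`) so that frame or
unit mismatches fail loudly instead of silently corrupting positions.
Millimetre<->pixel conversion divides by a single isotropic voxel pitch and
keeps continuous (sub-voxel) pixel coordinates; rounding to integer voxel
indices happens only at lookup time, elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

FrameTag = Literal["H", "US"]
UnitTag = Literal["mm", "px"]

__all__ = [
    "Point3",
    "RigidTranslation",
    "FrameMismatchError",
    "transform_point",
    "inverse_transform_point",
    "mm_to_px",
    "px_to_mm",
    "estimate_translation",
    "CalibrationResult",
]


class FrameMismatchError(ValueError):
    """Raised when point arithmetic mixes incompatible frame or unit tags."""


@dataclass(frozen=True)
class Point3:
    """A tagged 3-vector: ``values`` in order (x, y, z) of ``frame``/``units``."""

    values: np.ndarray
    frame: FrameTag
    units: UnitTag = "mm"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3,):
            raise ValueError(f"Point3 needs exactly 3 components, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("Point3 components must be finite")
        object.__setattr__(self, "values", v)
        if self.frame not in ("H", "US"):
            raise ValueError(f"unknown frame tag {self.frame!r}")
        if self.units not in ("mm", "px"):
            raise ValueError(f"unknown unit tag {self.units!r}")

    def require(self, frame: FrameTag | None = None, units: UnitTag | None = None) -> "Point3":
        if frame is not None and self.frame != frame:
            raise FrameMismatchError(f"expected frame {frame!r}, got {self.frame!r}")
        if units is not None and self.units != units:
            raise FrameMismatchError(f"expected units {units!r}, got {self.units!r}")
        return self


@dataclass(frozen=True)
class RigidTranslation:
    """Pure-translation rigid map from the hexapod frame to the US frame.

    ``offset`` is in millimetres: ``p_US = p_H + offset``. The parallel-axes
    assumption of the rig means no rotation component exists in this type.
    """

    offset: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.offset, dtype=float)
        if o.shape != (3,):
            raise ValueError("offset must be a 3-vector (mm)")
        if not np.all(np.isfinite(o)):
            raise ValueError("offset must be finite")
        object.__setattr__(self, "offset", o)


def transform_point(t: RigidTranslation, p: Point3) -> Point3:
    """Map a hexapod-frame point (mm) into the US frame."""
    p.require(frame="H", units="mm")
    return Point3(p.values + t.offset, frame="US", units="mm")


def inverse_transform_point(t: RigidTranslation, p: Point3) -> Point3:
    """Map a US-frame point (mm) back into the hexapod frame."""
    p.require(frame="US", units="mm")
    return Point3(p.values - t.offset, frame="H", units="mm")


def mm_to_px(p: Point3, pitch: float) -> Point3:
    """Convert a millimetre point to continuous pixel units (divide by pitch)."""
    if not (np.isfinite(pitch) and pitch > 0):
        raise ValueError(f"pitch must be a positive finite mm value, got {pitch}")
    p.require(units="mm")
    return Point3(p.values / pitch, frame=p.frame, units="px")


def px_to_mm(p: Point3, pitch: float) -> Point3:
    """Convert a continuous pixel point back to millimetres (multiply by pitch)."""
    if not (np.isfinite(pitch) and pitch > 0):
        raise ValueError(f"pitch must be a positive finite mm value, got {pitch}")
    p.require(units="px")
    return Point3(p.values * pitch, frame=p.frame, units="mm")


@dataclass
class CalibrationResult:
    """Estimated H->US translation with residual diagnostics."""

    translation: RigidTranslation
    n_pairs: int
    method: str
    residual_rms_mm: float
    residual_mean_abs_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def to_dict(self) -> dict:
        return {
            "offset_mm": self.translation.offset.tolist(),
            "n_pairs": self.n_pairs,
            "method": self.method,
            "residual_rms_mm": self.residual_rms_mm,
            "residual_mean_abs_mm": self.residual_mean_abs_mm.tolist(),
        }


def _as_pair_arrays(
    pairs: Iterable[tuple[Point3, Point3]],
) -> tuple[np.ndarray, np.ndarray]:
    det, hex_ = [], []
    for p_us, p_h in pairs:
        det.append(p_us.require(frame="US", units="mm").values)
        hex_.append(p_h.require(frame="H", units="mm").values)
    if not det:
        raise ValueError("calibration needs at least one (detected_US, tip_H) pair")
    return np.asarray(det), np.asarray(hex_)


def estimate_translation(
    pairs: Sequence[tuple[Point3, Point3]],
    method: str = "least_squares",
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CalibrationResult:
    """Estimate the H->US translation offset from detected/commanded tip pairs.

    The rig calibration minimizes the mean discrepancy between needle tips
    detected in US volumes and the corresponding hexapod poses. Under a pure
    translation model the least-squares solution is closed form: the
    componentwise mean of ``detected_US - tip_H``. ``method="least_absolute"``
    instead computes the geometric median of the differences (Weiszfeld
    iteration), which is robust to outlier detections but not the default.
    """
    det, hex_ = _as_pair_arrays(pairs)
    diffs = det - hex_
    if method == "least_squares":
        offset = diffs.mean(axis=0)
    elif method == "least_absolute":
        offset = _geometric_median(diffs, max_iter=max_iter, tol=tol)
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    resid = diffs - offset
    return CalibrationResult(
        translation=RigidTranslation(offset),
        n_pairs=len(diffs),
        method=method,
        residual_rms_mm=float(np.sqrt(np.mean(resid**2))),
        residual_mean_abs_mm=np.abs(resid).mean(axis=0),
    )


def _geometric_median(x: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    # Weiszfeld fixed-point iteration; exact-hit points handled by the
    # standard epsilon guard.
    y = x.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(x - y, axis=1)
        d = np.maximum(d, 1e-12)
        w = 1.0 / d
        y_new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y
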