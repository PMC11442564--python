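"""Synthetic low-resolution 3D ultrasound insertion sequences with exact ground truth.

This module stands in for a robot/probe acquisition rig: a hexapod drives a
2.15 mm trocar needle through water or liver-like tissue while a 16x16-element
matrix transducer records B-mode volumes at 4 Hz. Real beamformed data from
such a rig are not publicly available, so the simulator emulates the
acquisition geometry exactly (voxel lattice, field of view, insertion
kinematics, start-position grid) and the image appearance approximately
(speckle statistics, tissue structures, needle echo and reverberation), with
the decisive advantage that every frame carries exact ground truth.

Geometry conventions
--------------------
Volumes are arrays in ``(depth z, lateral x, lateral y)`` axis order, matching
the printed acquisition shape 117 x 134 x 134 at 0.3 mm isotropic pitch with a
depth field of view of 5-40 mm. Points are ``(x, y, z)`` millimetre vectors;
:class:`VolumeGrid` maps between the two. With zero tilt the needle advances
along the negative ``y_US`` axis, i.e. ``(0, 0, -1)`` in array-axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .coords import RigidTranslation

__all__ = [
    "VolumeGrid",
    "TransducerSpec",
    "NeedleSpec",
    "MediumSpec",
    "TrajectorySpec",
    "Frame",
    "InsertionRecord",
    "InvalidSpecError",
    "ConfigurationError",
    "DEFAULT_TRANSFORM",
    "PARALLEL_Z_H",
    "PARALLEL_X_H",
    "TILTED_ANGLES",
    "make_trajectory",
    "render_volume",
    "render_background",
    "simulate_insertion",
    "generate_dataset",
    "dataset_manifest",
]


class InvalidSpecError(ValueError):
    """A simulation spec violates its invariants (non-finite or non-positive)."""


class ConfigurationError(ValueError):
    """A protocol/transform combination cannot produce in-FOV data."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice geometry tying array indices to US-frame millimetres.

    Parameters
    ----------
    shape : (int, int, int)
        Voxel counts in (depth, x_US, y_US) order. Default 117 x 134 x 134.
    pitch : float
        Isotropic voxel pitch in mm (default 0.3).
    depth_min : float
        Depth (z_US) of voxel index 0 in mm (default 5, top of the FOV).
    lateral_origin : (float, float)
        mm coordinate of index 0 on the x_US and y_US axes (default 0).
    """

    shape: tuple[int, int, int] = (117, 134, 134)
    pitch: float = 0.3
    depth_min: float = 5.0
    lateral_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise InvalidSpecError(f"grid shape entries must be >= 1, got {self.shape}")
        if not (np.isfinite(self.pitch) and self.pitch > 0):
            raise InvalidSpecError(f"pitch must be positive, got {self.pitch}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @classmethod
    def from_fov(
        cls,
        depth_range_mm: tuple[float, float] = (5.0, 40.0),
        lateral_extent_mm: float = 40.2,
        pitch: float = 0.3,
    ) -> "VolumeGrid":
        """Build a grid covering the stated FOV: voxel count = ceil(extent/pitch)."""
        lo, hi = depth_range_mm
        if hi <= lo or lateral_extent_mm <= 0:
            raise InvalidSpecError("FOV extents must be positive")
        nd = int(np.ceil((hi - lo) / pitch - 1e-9))
        nl = int(np.ceil(lateral_extent_mm / pitch - 1e-9))
        return cls(shape=(nd, nl, nl), pitch=pitch, depth_min=lo)

    @property
    def origin_mm(self) -> np.ndarray:
        """(x, y, z) mm position of voxel (0, 0, 0)."""
        ox, oy = self.lateral_origin
        return np.array([ox, oy, self.depth_min])

    def extent_mm(self) -> np.ndarray:
        """(x, y, z) mm position just past the last voxel."""
        nz, nx, ny = self.shape
        return self.origin_mm + self.pitch * np.array([nx, ny, nz])

    def mm_to_index(self, p_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel index (z, x, y) of an (x, y, z) US-frame mm point."""
        x, y, z = np.asarray(p_mm, dtype=float)
        ox, oy = self.lateral_origin
        return np.array(
            [(z - self.depth_min), (x - ox), (y - oy)], dtype=float
        ) / self.pitch

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """(x, y, z) mm coordinate of a (z, x, y) voxel index (voxel center at integers)."""
        iz, ix, iy = np.asarray(idx, dtype=float)
        ox, oy = self.lateral_origin
        return np.array(
            [ox + ix * self.pitch, oy + iy * self.pitch, self.depth_min + iz * self.pitch]
        )

    def margin_voxels(self, p_mm: np.ndarray) -> float:
        """Distance (in voxels) of a point from the nearest FOV face; <0 = outside."""
        idx = self.mm_to_index(p_mm)
        hi = np.array(self.shape, dtype=float) - 1.0
        return float(np.min(np.minimum(idx, hi - idx)))

    def contains(self, p_mm: np.ndarray, margin_voxels: float = 0.0) -> bool:
        return self.margin_voxels(p_mm) >= margin_voxels

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates (z, x, y) in mm."""
        nz, nx, ny = self.shape
        ox, oy = self.lateral_origin
        return (
            self.depth_min + self.pitch * np.arange(nz),
            ox + self.pitch * np.arange(nx),
            oy + self.pitch * np.arange(ny),
        )


@dataclass(frozen=True)
class TransducerSpec:
    """Matrix-array transducer: an ``nx x ny`` element grid, one channel each.

    Wiring every element to its own system channel avoids multiplexing, which
    is what makes the 4 Hz volume rate possible at the cost of resolution.
    """

    elements: tuple[int, int] = (16, 16)
    pitch_mm: float = 0.3
    center_frequency_mhz: float = 3.0

    @property
    def channels(self) -> int:
        return int(self.elements[0]) * int(self.elements[1])


@dataclass(frozen=True)
class NeedleSpec:
    """Needle appearance: a bright cylinder ending at the tip.

    The physical needle has a trocar (three-faceted) point; the simulator
    renders a flat end cap since the tip *position*, not its morphology, is
    the learning target at 0.3 mm pitch.
    """

    diameter: float = 2.15  # mm
    echo_intensity: float = 255.0  # 8-bit level of the needle core
    blur_sigma: float = 0.3  # mm point-spread smoothing per axis
    reverb_strength: float = 0.0  # relative amplitude of the reverberation tail

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise InvalidSpecError("needle diameter must be positive")
        if not (0 <= self.echo_intensity <= 255):
            raise InvalidSpecError("echo_intensity must be an 8-bit level")
        if self.blur_sigma < 0 or self.reverb_strength < 0:
            raise InvalidSpecError("blur_sigma and reverb_strength must be >= 0")


@dataclass(frozen=True)
class MediumSpec:
    """Imaging-medium appearance model.

    Background is a smooth base level (plus, for liver, random ellipsoidal
    inclusions and thin bright boundary sheets) modulated by multiplicative
    Rayleigh speckle and additive Gaussian sensor noise, quantized to 8 bits.
    Liver tissue contains more structures and boundaries than water, which is
    what degrades detection there.
    """

    kind: Literal["water", "liver"]
    background_level: float
    speckle_scale: float
    structure_count: int = 0
    structure_contrast: float = 0.0
    sensor_noise: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("water", "liver"):
            raise InvalidSpecError(f"unknown medium kind {self.kind!r}")
        if self.kind == "water" and self.structure_count != 0:
            raise InvalidSpecError("water medium has no structures")

    @classmethod
    def water(cls) -> "MediumSpec":
        return cls(kind="water", background_level=12.0, speckle_scale=0.08)

    @classmethod
    def liver(cls) -> "MediumSpec":
        return cls(
            kind="liver",
            background_level=40.0,
            speckle_scale=0.40,
            structure_count=10,
            structure_contrast=30.0,
            sensor_noise=3.0,
        )


@dataclass(frozen=True)
class TrajectorySpec:
    """One straight insertion: start pose, tilt, velocity, travel, frame rate.

    ``alpha_x``/``alpha_z`` tilt the insertion axis about the hexapod x/z axes
    in degrees; at zero tilt the needle advances along -y (the negative y_US
    axis under the parallel-axes rig assumption).
    """

    start_H: tuple[float, float, float]  # (x, y, z) mm, hexapod frame
    alpha_x: float = 0.0  # degrees about x_H
    alpha_z: float = 0.0  # degrees about z_H
    velocity: float = 1.5  # mm/s
    distance: float = 15.0  # mm
    frame_rate: float = 4.0  # Hz

    def __post_init__(self) -> None:
        vals = (*self.start_H, self.alpha_x, self.alpha_z, self.velocity, self.distance, self.frame_rate)
        if not np.all(np.isfinite(vals)):
            raise InvalidSpecError("trajectory parameters must be finite")
        if self.velocity <= 0 or self.distance <= 0 or self.frame_rate <= 0:
            raise InvalidSpecError("velocity, distance and frame_rate must be positive")

    def direction(self) -> np.ndarray:
        """Unit insertion direction (x, y, z); (0, -1, 0) at zero tilt."""
        az = np.deg2rad(self.alpha_z)
        ax = np.deg2rad(self.alpha_x)
        d = np.array([0.0, -1.0, 0.0])
        rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
        rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
        d = rx @ rz @ d
        return d / np.linalg.norm(d)


@dataclass
class Frame:
    """One acquired volume plus its exact tip ground truth in both frames."""

    volume: np.ndarray  # uint8, (depth, x, y)
    timestamp: float  # s
    tip_H: np.ndarray  # (x, y, z) mm
    tip_US: np.ndarray  # (x, y, z) mm
    tip_in_fov: bool = True

    def tip_US_px(self, pitch: float) -> np.ndarray:
        return self.tip_US / pitch


@dataclass
class InsertionRecord:
    """An ordered sequence of frames from a single needle insertion."""

    id: str
    medium: MediumSpec
    trajectory: TrajectorySpec
    frames: list[Frame]
    seed: int
    transform: RigidTranslation = field(default_factory=lambda: RigidTranslation(np.zeros(3)))

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# Default rig placement: maps the protocol's hexapod start grid into the FOV
# (x_US in 15-25 mm, y_US start 32 mm, z_US in 10-20 mm).
DEFAULT_TRANSFORM = RigidTranslation(np.array([40.0, 32.0, 28.0]))

# Insertion start grids (hexapod frame, mm).
PARALLEL_Z_H = (-8.0, -10.0, -13.0, -18.0)
PARALLEL_X_H = (-15.0, -20.0, -25.0)
TILTED_Z_H = (-9.0, -13.0, -17.0)
TILTED_X_H = (-15.0, -20.0, -25.0)
# (alpha_x, alpha_z) degree pairs of the tilted protocol.
TILTED_ANGLES = ((0.0, 5.0), (0.0, -5.0), (-5.0, 0.0))


def make_trajectory(spec: TrajectorySpec) -> list[tuple[float, np.ndarray]]:
    """Sample (timestamp, tip_H) poses of one insertion.

    Poses start at t=0 and advance by ``velocity / frame_rate`` mm along the
    (possibly tilted) insertion direction each frame, endpoints inclusive,
    until cumulative travel reaches ``distance``.
    """
    step = spec.velocity / spec.frame_rate
    n_steps = int(np.ceil(spec.distance / step - 1e-9))
    d = spec.direction()
    start = np.asarray(spec.start_H, dtype=float)
    return [(k / spec.frame_rate, start + k * step * d) for k in range(n_steps + 1)]


def _smooth_speckle(shape: tuple[int, ...], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-1 multiplicative speckle: Rayleigh field, lightly correlated."""
    if scale <= 0:
        return np.ones(shape)
    sigma = np.sqrt(2.0 / np.pi)  # Rayleigh scale giving unit mean
    r = rng.rayleigh(sigma, size=shape)
    r = ndimage.gaussian_filter(r, 0.7)  # grain ~ one voxel, like a PSF
    r /= r.mean()
    return 1.0 + scale * (r - 1.0)


def render_background(
    grid: VolumeGrid, medium: MediumSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render the medium without the needle (float, pre-quantization)."""
    zs, xs, ys = grid.axes_mm()
    base = np.full(grid.shape, float(medium.background_level))
    if medium.structure_count > 0:
        lo = grid.origin_mm
        hi = grid.extent_mm()
        zz = zs[:, None, None]
        xx = xs[None, :, None]
        yy = ys[None, None, :]
        n_sheets = max(1, medium.structure_count // 3)
        for _ in range(medium.structure_count):
            c = rng.uniform(lo, hi)  # (x, y, z)
            ax = rng.uniform(2.0, 8.0, size=3)  # semi-axes mm
            contrast = medium.structure_contrast * rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0])
            q = ((xx - c[0]) / ax[0]) ** 2 + ((yy - c[1]) / ax[1]) ** 2 + ((zz - c[2]) / ax[2]) ** 2
            base += contrast * np.exp(-1.5 * q)
        for _ in range(n_sheets):
            # thin bright boundary sheet: a plane through a random point
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            c = rng.uniform(lo, hi)
            dist = n[0] * (xx - c[0]) + n[1] * (yy - c[1]) + n[2] * (zz - c[2])
            amp = medium.structure_contrast * rng.uniform(1.2, 1.7)
            base += amp * np.exp(-0.5 * (dist / 0.6) ** 2)
    base = ndimage.gaussian_filter(base, 1.0)
    vol = base * _smooth_speckle(grid.shape, medium.speckle_scale, rng)
    if medium.sensor_noise > 0:
        vol = vol + rng.normal(0.0, medium.sensor_noise, size=grid.shape)
    return np.clip(vol, 0.0, 255.0)


def _render_needle(
    grid: VolumeGrid,
    needle: NeedleSpec,
    tip_US: np.ndarray,
    direction_US: np.ndarray,
) -> np.ndarray:
    """Needle echo image: bright cylinder of the given diameter ending at the tip."""
    zs, xs, ys = grid.axes_mm()
    d = np.asarray(direction_US, dtype=float)
    d = d / np.linalg.norm(d)
    # axial coordinate measured backwards from the tip towards the entry side
    ax_z = (zs[:, None, None] - tip_US[2]) * (-d[2])
    ax_x = (xs[None, :, None] - tip_US[0]) * (-d[0])
    ax_y = (ys[None, None, :] - tip_US[1]) * (-d[1])
    axial = ax_z + ax_x + ax_y
    r2 = (
        (zs[:, None, None] - tip_US[2]) ** 2
        + (xs[None, :, None] - tip_US[0]) ** 2
        + (ys[None, None, :] - tip_US[1]) ** 2
        - axial**2
    )
    radius = needle.diameter / 2.0
    core = (axial >= 0.0) & (r2 <= radius**2)
    img = np.zeros(grid.shape)
    img[core] = needle.echo_intensity
    sigma_vox = needle.blur_sigma / grid.pitch
    if sigma_vox > 0:
        img = ndimage.gaussian_filter(img, sigma_vox)
    if needle.reverb_strength > 0:
        # comet-tail: attenuated replicas of the shaft at greater depth
        shift = max(1, int(round(needle.diameter / grid.pitch)))
        tail = np.zeros_like(img)
        for k in (1, 2, 3):
            amp = needle.reverb_strength**k
            tail[k * shift :] = np.maximum(tail[k * shift :], amp * img[: -k * shift or None])
        img = np.maximum(img, tail)
    return img


def render_volume(
    grid: VolumeGrid,
    medium: MediumSpec,
    needle: NeedleSpec,
    tip_H: np.ndarray,
    transform: RigidTranslation,
    rng: np.random.Generator,
    direction_H: np.ndarray = (0.0, -1.0, 0.0),
) -> tuple[np.ndarray, dict]:
    """Render one 8-bit frame; returns (volume, metadata).

    The needle is drawn whenever any part of it intersects the FOV; a tip far
    outside the lateral FOV yields a pure-background volume, flagged by
    ``metadata["tip_in_fov"]``. Identical inputs and generator state give
    bit-identical output.
    """
    tip_US = np.asarray(tip_H, dtype=float) + transform.offset
    bg = render_background(grid, medium, rng)
    meta = {"tip_in_fov": grid.contains(tip_US), "tip_margin_voxels": grid.margin_voxels(tip_US)}
    # skip the needle only when the whole shaft is far from the FOV
    diag = float(np.linalg.norm(grid.extent_mm() - grid.origin_mm))
    center = (grid.origin_mm + grid.extent_mm()) / 2.0
    if np.linalg.norm(tip_US - center) > diag + 50.0 and not meta["tip_in_fov"]:
        vol = bg
    else:
        needle_img = _render_needle(grid, needle, tip_US, np.asarray(direction_H, dtype=float))
        vol = np.maximum(bg, needle_img)
    return np.clip(np.round(vol), 0, 255).astype(np.uint8), meta


def simulate_insertion(
    grid: VolumeGrid,
    medium: MediumSpec,
    needle: NeedleSpec,
    spec: TrajectorySpec,
    transform: RigidTranslation = DEFAULT_TRANSFORM,
    seed: int = 0,
    insertion_id: str = "ins",
) -> InsertionRecord:
    """Simulate one insertion: one frame per trajectory pose, reproducible from seed."""
    poses = make_trajectory(spec)
    d = spec.direction()
    frames: list[Frame] = []
    # one child stream per frame so records are reproducible regardless of
    # how many frames a caller renders
    streams = np.random.SeedSequence(seed).spawn(len(poses))
    for (t, tip_H), ss in zip(poses, streams):
        rng = np.random.default_rng(ss)
        vol, meta = render_volume(grid, medium, needle, tip_H, transform, rng, direction_H=d)
        frames.append(
            Frame(
                volume=vol,
                timestamp=t,
                tip_H=tip_H,
                tip_US=tip_H + transform.offset,
                tip_in_fov=meta["tip_in_fov"],
            )
        )
    return InsertionRecord(
        id=insertion_id, medium=medium, trajectory=spec, frames=frames, seed=seed,
        transform=transform,
    )


def _protocol_specs(protocol: str) -> list[TrajectorySpec]:
    if protocol == "parallel":
        return [
            TrajectorySpec(start_H=(x, 0.0, z), velocity=1.5)
            for z in PARALLEL_Z_H
            for x in PARALLEL_X_H
        ]
    if protocol == "tilted":
        return [
            TrajectorySpec(start_H=(x, 0.0, z), alpha_x=ax, alpha_z=az, velocity=1.0)
            for (ax, az) in TILTED_ANGLES
            for z in TILTED_Z_H
            for x in TILTED_X_H
        ]
    raise ConfigurationError(f"unknown protocol {protocol!r}; expected 'parallel' or 'tilted'")


def generate_dataset(
    protocol: Literal["parallel", "tilted"],
    grid: VolumeGrid | None = None,
    medium: MediumSpec | None = None,
    needle: NeedleSpec | None = None,
    transform: RigidTranslation = DEFAULT_TRANSFORM,
    seed: int = 0,
    frame_rate: float = 4.0,
) -> list[InsertionRecord]:
    """Generate the full insertion protocol as a list of records.

    ``parallel``: 12 insertions (4 heights x 3 horizontal positions) at
    1.5 mm/s. ``tilted``: 27 insertions (9 per tilt angle) at 1.0 mm/s.
    Both travel 15 mm at 4 Hz.
    """
    grid = grid or VolumeGrid()
    medium = medium or MediumSpec.water()
    needle = needle or NeedleSpec()
    specs = [replace(s, frame_rate=frame_rate) for s in _protocol_specs(protocol)]
    for s in specs:
        poses = make_trajectory(s)
        if not any(grid.contains(tip + transform.offset) for _, tip in poses):
            raise ConfigurationError(
                f"trajectory starting at {s.start_H} lies entirely outside the FOV"
            )
    seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
    records = []
    for i, (s, si) in enumerate(zip(specs, seeds)):
        rec = simulate_insertion(
            grid, medium, needle, s, transform, seed=int(si),
            insertion_id=f"{protocol}_{i:02d}",
        )
        records.append(rec)
    return records


def dataset_manifest(records: Sequence[InsertionRecord], pitch: float | None = None):
    """Per-frame manifest as a pandas DataFrame (ground truth in both frames/units)."""
    import pandas as pd

    rows = []
    for rec in records:
        p = pitch if pitch is not None else 0.3
        for k, f in enumerate(rec.frames):
            px = f.tip_US_px(p)
            rows.append(
                {
                    "insertion_id": rec.id,
                    "frame_idx": k,
                    "timestamp_s": f.timestamp,
                    "tip_H_x_mm": f.tip_H[0],
                    "tip_H_y_mm": f.tip_H[1],
                    "tip_H_z_mm": f.tip_H[2],
                    "tip_US_x_mm": f.tip_US[0],
                    "tip_US_y_mm": f.tip_US[1],
                    "tip_US_z_mm": f.tip_US[2],
                    "tip_US_x_px": px[0],
                    "tip_US_y_px": px[1],
                    "tip_US_z_px": px[2],
                    "medium": rec.medium.kind,
                    "alpha_x": rec.trajectory.alpha_x,
                    "alpha_z": rec.trajectory.alpha_z,
                    "start_x_H": rec.trajectory.start_H[0],
                    "start_z_H": rec.trajectory.start_H[2],
                    "tip_in_fov": f.tip_in_fov,
                    "seed": rec.seed,
                }
            )
    return pd.DataFrame(rows)
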