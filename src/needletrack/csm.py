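"""Conventional segmentation method (CSM) for needle-tip detection.

The deterministic three-stage baseline against which the learned regressor is
compared:

1. **ROI search** — the needle is assumed to be the largest structure in the
   volume: median-filter, binarize above an 8-bit threshold, take the largest
   connected component and center a region of interest on its centroid
   (cropped laterally and in depth, never along the insertion axis y_US).
2. **Segmentation** — a fast-marching front is seeded at the brightest ROI
   voxel of the *original* (unfiltered) image and propagated with speeds
   derived from grayscale differences to the seed; thresholding first-arrival
   times yields the needle mask.
3. **Tip extraction** — the tip is the mask voxel farthest along the known
   insertion direction from the entry side of the structure.

The pipeline contains no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import rank

from .coords import Point3
from .phantom_sim import VolumeGrid

__all__ = [
    "CSMParams",
    "ROIBox",
    "SegmentationMask",
    "TipEstimate",
    "NoStructureError",
    "find_needle_roi",
    "segment_needle",
    "locate_tip",
    "detect_tip_csm",
]


class NoStructureError(RuntimeError):
    """No voxel above the intensity threshold: nothing to detect in this frame."""


@dataclass(frozen=True)
class CSMParams:
    """Tunable parameters of the conventional pipeline.

    ``median_size`` is in array order (depth, x_US, y_US); the default
    (3, 3, 25) places the 25-voxel extent of the filter on the y_US axis so
    the elongated kernel preserves the elongated needle.  ``fmm_beta`` sets
    the contrast sensitivity of the front speed 1/(1 + beta*|I - I(seed)|)
    and ``fmm_tau`` the arrival-time cutoff; both were fixed once against the
    synthetic bright-cylinder fixture.
    """

    median_size: tuple[int, int, int] = (3, 3, 25)
    intensity_threshold: int = 128
    roi_halfwidth: int = 25
    connectivity: int = 26
    fmm_beta: float = 0.5
    fmm_tau: float = 160.0

    def __post_init__(self) -> None:
        if any(s < 1 or s % 2 == 0 for s in self.median_size):
            raise ValueError("median sizes must be odd and >= 1")
        if not (0 < self.intensity_threshold < 255):
            raise ValueError("intensity_threshold must lie strictly inside (0, 255)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.roi_halfwidth < 1 or self.fmm_beta < 0 or self.fmm_tau < 0:
            raise ValueError("roi_halfwidth must be >= 1; fmm parameters >= 0")

    @property
    def label_structure(self) -> np.ndarray:
        rank_ = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank_)

    @classmethod
    def for_pitch(cls, pitch: float, base_pitch: float = 0.3, **overrides) -> "CSMParams":
        """Rescale the voxel-unit defaults to a coarser/finer lattice.

        The stock parameters are calibrated for the 0.3 mm acquisition grid;
        filter extents, the ROI half-width and the arrival cutoff all scale
        with 1/pitch so the same physical sizes are covered.
        """
        f = base_pitch / pitch
        base = cls()

        def odd(v: float) -> int:
            n = max(1, int(round(v)))
            return n if n % 2 else n + 1

        params = dict(
            median_size=tuple(odd(s * f) for s in base.median_size),
            roi_halfwidth=max(1, int(round(base.roi_halfwidth * f))),
            fmm_tau=base.fmm_tau * f,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class ROIBox:
    """Half-open index intervals (depth, x, y) into the parent grid."""

    z: tuple[int, int]
    x: tuple[int, int]
    y: tuple[int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.z), slice(*self.x), slice(*self.y))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.z[1] - self.z[0], self.x[1] - self.x[0], self.y[1] - self.y[0])

    @property
    def offset(self) -> np.ndarray:
        return np.array([self.z[0], self.x[0], self.y[0]])

    def __post_init__(self) -> None:
        if any(b <= a for a, b in (self.z, self.x, self.y)):
            raise ValueError(f"degenerate ROI {self}")


@dataclass
class SegmentationMask:
    """Binary needle mask aligned to its ROI, with the propagation seed."""

    mask: np.ndarray  # bool, ROI-shaped
    seed: tuple[int, int, int]  # local (z, x, y) index within the ROI
    roi: ROIBox

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("segmentation mask is empty")
        if not self.mask[self.seed]:
            raise ValueError("seed must lie inside the mask")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def global_indices(self) -> np.ndarray:
        return np.argwhere(self.mask) + self.roi.offset


@dataclass
class TipEstimate:
    """A detected or predicted needle-tip position with provenance."""

    position: Point3
    method: str
    frame_index: int | None = None
    diagnostics: dict = field(default_factory=dict)


def _as_uint8(volume: np.ndarray) -> np.ndarray:
    """8-bit view of a volume; other scales are min-max rescaled first."""
    if volume.dtype == np.uint8:
        return volume
    v = np.asarray(volume, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.zeros(v.shape, np.uint8)
    return np.round((v - lo) / (hi - lo) * 255).astype(np.uint8)


def find_needle_roi(
    volume: np.ndarray, params: CSMParams = CSMParams()
) -> tuple[ROIBox, np.ndarray]:
    """Locate the needle-bearing region of interest.

    Median-filters the volume, thresholds it, selects the largest connected
    component (ties broken by brighter mean intensity in the original image)
    and centers the ROI on its centroid: ±roi_halfwidth voxels in depth and
    x_US, the full y_US extent, clamped to the volume bounds.

    Returns (roi, centroid) with the centroid in (z, x, y) voxel coordinates.
    """
    vol = _as_uint8(volume)
    filtered = rank.median(vol, footprint=np.ones(params.median_size, bool))
    binary = filtered > params.intensity_threshold
    if not binary.any():
        raise NoStructureError(
            f"no voxel above threshold {params.intensity_threshold} after median filtering"
        )
    labels, n = ndimage.label(binary, structure=params.label_structure)
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        means = ndimage.mean(vol, labels=labels, index=best)
        best = best[np.argsort(means)[::-1]]
    component = labels == best[0]
    centroid = np.array(ndimage.center_of_mass(component))
    nz, nx, ny = vol.shape
    hw = params.roi_halfwidth
    cz, cx, _ = np.round(centroid).astype(int)
    roi = ROIBox(
        z=(max(0, cz - hw), min(nz, cz + hw + 1)),
        x=(max(0, cx - hw), min(nx, cx + hw + 1)),
        y=(0, ny),
    )
    return roi, centroid


def _fast_marching_arrival(speed: np.ndarray, seed: tuple[int, int, int], stop: float) -> np.ndarray:
    """First-arrival times of a front over ``speed``, seeded at one voxel."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(speed, dtype=np.float64))
    fm = sitk.FastMarchingImageFilter()
    # sitk indexes (x, y, z) = reversed numpy axis order
    fm.SetTrialPoints([tuple(int(i) for i in seed[::-1])])
    fm.SetStoppingValue(float(stop))
    arrival = sitk.GetArrayFromImage(fm.Execute(img))
    return arrival


def segment_needle(
    volume: np.ndarray, roi: ROIBox, params: CSMParams = CSMParams()
) -> SegmentationMask:
    """Segment the needle inside the ROI of the original (unfiltered) volume.

    The front is seeded at the maximum-intensity ROI voxel (ties resolved to
    the voxel closest to the ROI center) and moves with speed
    ``1 / (1 + fmm_beta * |I(v) - I(seed)|)``; voxels reached within
    ``fmm_tau`` form the mask, restricted to the connected component of the
    seed.
    """
    crop = _as_uint8(np.asarray(volume)[roi.slices()])
    if crop.size == 0:
        raise ValueError("degenerate ROI: empty crop")
    flat = np.argwhere(crop == crop.max())
    center = (np.array(crop.shape) - 1) / 2.0
    seed = tuple(int(v) for v in flat[np.argmin(((flat - center) ** 2).sum(axis=1))])
    intens = crop.astype(float)
    speed = 1.0 / (1.0 + params.fmm_beta * np.abs(intens - intens[seed]))
    if params.fmm_tau == 0:
        mask = np.zeros(crop.shape, bool)
        mask[seed] = True
        return SegmentationMask(mask=mask, seed=seed, roi=roi)
    arrival = _fast_marching_arrival(speed, seed, stop=params.fmm_tau * 1.5)
    mask = arrival <= params.fmm_tau
    labels, _ = ndimage.label(mask, structure=params.label_structure)
    mask = labels == labels[seed]
    return SegmentationMask(mask=mask, seed=seed, roi=roi)


def locate_tip(
    mask: SegmentationMask,
    insertion_direction: np.ndarray = (0.0, -1.0, 0.0),
    tie_break: str = "centroid",
) -> np.ndarray:
    """Tip voxel = mask voxel with extreme projection onto the advance direction.

    ``insertion_direction`` is an (x, y, z) unit vector; the tip is the voxel
    farthest along it from the entry side, i.e. the farthest point of the
    segmented structure from its entry edge. When several voxels tie at the
    extreme projection (the flat end cap of a needle fills a whole lattice
    plane), ``tie_break`` selects among them:

    ``"centroid"`` (default)
        the voxel nearest the centroid of the tied set — for an end cap this
        recovers the needle axis to sub-voxel accuracy instead of drifting to
        the cap rim;
    ``"entry_face"``
        the voxel farthest from the entry-face centroid of the mask, which
        prefers the geometrically most advanced corner.

    Remaining ties are broken lexicographically so the result is fully
    deterministic. Returns the (z, x, y) voxel index in the parent volume.
    """
    d = np.asarray(insertion_direction, dtype=float)
    if not d.any():
        raise ValueError("insertion direction must be non-zero")
    d = d / np.linalg.norm(d)
    axis_dir = np.array([d[2], d[0], d[1]])  # to (z, x, y) array order
    vox = mask.global_indices().astype(float)
    proj = vox @ axis_dir
    top = proj.max()
    cand = vox[proj >= top - 1e-9]
    if len(cand) > 1:
        if tie_break == "centroid":
            score = -((cand - cand.mean(axis=0)) ** 2).sum(axis=1)
        elif tie_break == "entry_face":
            entry = vox[proj <= proj.min() + 0.5]
            score = ((cand - entry.mean(axis=0)) ** 2).sum(axis=1)
        else:
            raise ValueError(f"unknown tie_break {tie_break!r}")
        cand = cand[score >= score.max() - 1e-9]
        cand = cand[np.lexsort(cand.T[::-1])]
    return cand[0].astype(int)


def detect_tip_csm(
    volume: np.ndarray,
    params: CSMParams = CSMParams(),
    grid: VolumeGrid = VolumeGrid(),
    direction: np.ndarray = (0.0, -1.0, 0.0),
    frame_index: int | None = None,
) -> TipEstimate:
    """Full conventional pipeline: ROI, segmentation, tip, in US millimetres.

    Raises :class:`NoStructureError` when the frame contains nothing above the
    detection threshold; the caller may record "no detection" for that frame.
    """
    roi, centroid = find_needle_roi(volume, params)
    seg = segment_needle(volume, roi, params)
    tip_idx = locate_tip(seg, direction)
    tip_mm = grid.index_to_mm(tip_idx)
    return TipEstimate(
        position=Point3(tip_mm, frame="US", units="mm"),
        method="csm",
        frame_index=frame_index,
        diagnostics={
            "roi": roi,
            "roi_centroid": centroid,
            "mask_voxels": seg.voxel_count,
            "seed": tuple(int(s) for s in (seg.roi.offset + np.array(seg.seed))),
            "tip_index": tuple(int(i) for i in tip_idx),
        },
    )
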