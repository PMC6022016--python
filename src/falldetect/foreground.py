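"""Person segmentation by background subtraction and blob analysis.

The chain is: per-pixel relative change test against a clean background
(threshold 15% of each background pixel by default), distance-transform
suppression of thin noise, disk erosion, border-anchored hole filling, then
connected-component filtering that discards anything smaller than the
minimum person size and keeps the largest survivor.  Frames without a
surviving component yield ``None`` and are skipped downstream.

Coordinates are 0-based with the origin at the top-left, y growing downward;
bounding boxes are half-open ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "PersonBlob",
    "to_grayscale",
    "estimate_background",
    "detect_change",
    "refine_mask",
    "extract_person_blob",
    "segment_frame",
    "segment_sequence",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the segmentation chain.

    ``change_fraction`` — per-pixel relative threshold on |frame − background|.
    ``distance_floor`` — pixels whose Euclidean distance-to-background inside
    the changed region is below this are dropped (thin-structure noise).
    ``min_person_size`` — smallest component kept; values < 1 are read as a
    fraction of the frame area, values >= 1 as absolute pixels.
    """

    change_fraction: float = 0.15
    distance_floor: float = 2.0
    erosion_radius: int = 1
    min_person_size: float = 0.005
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.change_fraction < 1.0:
            raise ValueError("change_fraction must be in (0, 1)")
        if self.min_person_size <= 0:
            raise ValueError("min_person_size must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.distance_floor < 0 or self.erosion_radius < 0:
            raise ValueError("distance_floor and erosion_radius must be >= 0")

    def min_size_pixels(self, frame_shape: tuple[int, int]) -> int:
        if self.min_person_size < 1.0:
            return max(1, int(round(self.min_person_size * frame_shape[0] * frame_shape[1])))
        return int(self.min_person_size)


@dataclass
class PersonBlob:
    """The segmented foreground component assumed to be the person."""

    mask: np.ndarray  # (H, W) bool, the component only
    bbox: tuple[int, int, int, int]  # (x, y, w, h), half-open
    centroid: tuple[float, float]  # (x, y), mean of member pixels
    boundary_points: np.ndarray  # (n, 2) int, (x, y) of edge pixels
    area: int


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to luma (ITU-R 601); pass grayscale through."""
    if frame.ndim == 2:
        return np.asarray(frame, dtype=np.float64)
    rgb = np.asarray(frame, dtype=np.float64)[..., :3]
    return rgb @ np.array([0.299, 0.587, 0.114])


def estimate_background(frames: np.ndarray, n_frames: int | None = 60) -> np.ndarray:
    """Pixel-wise temporal median of the first ``n_frames`` frames.

    A stand-in for a dedicated background-modelling algorithm: the median is
    robust as long as the person covers each pixel in fewer than half of the
    sampled frames.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (T, H, W) stack")
    if n_frames is None:
        n_frames = frames.shape[0]
    if n_frames > frames.shape[0]:
        raise ValueError(
            f"n_frames={n_frames} exceeds sequence length {frames.shape[0]}"
        )
    med = np.median(frames[:n_frames].astype(np.float64), axis=0)
    return np.clip(np.rint(med), 0, 255).astype(frames.dtype)


def detect_change(
    frame: np.ndarray, background: np.ndarray, change_fraction: float = 0.15
) -> np.ndarray:
    """Pixels whose change exceeds ``change_fraction`` of the background pixel.

    The comparison is per background pixel; a 1-intensity-unit floor guards
    the zero-background degeneracy (otherwise any change at a black pixel
    would trip the test).
    """
    f = to_grayscale(frame)
    b = to_grayscale(background)
    if f.shape != b.shape:
        raise ValueError(f"frame shape {f.shape} != background shape {b.shape}")
    return np.abs(f - b) > change_fraction * np.maximum(b, 1.0)


def refine_mask(change_mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Noise suppression and morphology over the raw change mask.

    Euclidean distance transform inside the changed region, dropping pixels
    closer than ``distance_floor`` to the unchanged region (kills speckles and
    thin streaks); disk erosion; then interior holes filled (flood fill from
    the frame border on the complement — anything not reachable from the
    border is interior and turned on).
    """
    mask = np.asarray(change_mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    out = mask
    if params.distance_floor > 0:
        dist = ndi.distance_transform_edt(out)
        out = dist >= params.distance_floor
    if params.erosion_radius > 0:
        out = ndi.binary_erosion(
            out, structure=disk(params.erosion_radius).astype(bool), border_value=0
        )
    out = ndi.binary_fill_holes(out)
    return out


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Edge pixels of the component: members with a 4-neighbour outside the
    component (pixels on the frame border count as boundary)."""
    eroded = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    ys, xs = np.nonzero(mask & ~eroded)
    return np.column_stack([xs, ys])


def extract_person_blob(
    mask: np.ndarray, params: SegmentationParams
) -> PersonBlob | None:
    """Largest connected component not smaller than the minimum person size.

    Returns ``None`` when no component survives the size filter — such frames
    do not contain a full person and are skipped downstream.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    structure = ndi.generate_binary_structure(2, 2 if params.connectivity == 8 else 1)
    labeled, n_comp = ndi.label(mask, structure=structure)
    if n_comp == 0:
        return None
    areas = np.bincount(labeled.ravel())[1:]
    min_size = params.min_size_pixels(mask.shape)
    survivors = np.nonzero(areas >= min_size)[0] + 1
    if survivors.size == 0:
        return None
    if survivors.size > 1:
        logger.warning(
            "%d components exceed the minimum person size; keeping the largest",
            survivors.size,
        )
    best = survivors[np.argmax(areas[survivors - 1])]
    comp = labeled == best
    ys, xs = np.nonzero(comp)
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    return PersonBlob(
        mask=comp,
        bbox=(x0, y0, x1 - x0 + 1, y1 - y0 + 1),
        centroid=(float(xs.mean()), float(ys.mean())),
        boundary_points=_boundary_points(comp),
        area=int(comp.sum()),
    )


def segment_frame(
    frame: np.ndarray, background: np.ndarray, params: SegmentationParams
) -> PersonBlob | None:
    """Full per-frame chain: change test, refinement, component filter."""
    change = detect_change(frame, background, params.change_fraction)
    refined = refine_mask(change, params)
    return extract_person_blob(refined, params)


def segment_sequence(
    frames: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    background: np.ndarray | None = None,
) -> list[PersonBlob | None]:
    """Segment every frame; estimates the background when none is supplied."""
    frames = np.asarray(frames)
    if background is None:
        background = estimate_background(frames, min(60, frames.shape[0]))
    return [segment_frame(f, background, params) for f in frames]
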