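"""Human-figure extraction from depth frames.

Stage order: background model -> foreground mask -> morphological
denoising -> largest-blob location -> arm rejection -> masked depth
profile. The output of the stage chain is a :class:`HumanBlob`: the
subject's tight bounding box, its binary mask and its masked depth
profile (depth where the mask is set, 0 elsewhere).

The background subtractor is deliberately a deterministic per-pixel
median + robust-spread model behind a pluggable interface: adaptive
mixture-of-Gaussians models or externally supplied masks (e.g. color
segmentation masks) can be dropped in via the same
:class:`ForegroundExtractor` protocol.

Coordinates are 0-based, origin top-left, x rightward, y downward;
boxes are half-open ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .io import DepthFrame

log = logging.getLogger(__name__)


class NoSubjectError(ValueError):
    """No foreground subject in this frame; the frame is skipped downstream."""


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel background depth statistics from leading background frames.

    ``reference`` is the per-pixel lower median (deterministic tie rule),
    ``spread`` a robust per-pixel scale (median absolute deviation).
    """

    reference: np.ndarray  # float64, (H, W)
    spread: np.ndarray     # float64, (H, W)
    frame_count: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference.shape


def build_background_model(frames: Sequence[DepthFrame | np.ndarray]) -> BackgroundModel:
    """Summarize leading background-only frames into a per-pixel model.

    Uses the lower median (element at index ``(B-1)//2`` of the sorted
    per-pixel stack) so ties between candidate medians resolve to the
    smaller value, keeping the model deterministic.
    """
    if len(frames) == 0:
        raise ValueError("background model needs at least one frame")
    stack = np.stack(
        [f.pixels if isinstance(f, DepthFrame) else np.asarray(f) for f in frames]
    ).astype(np.float64)
    b = stack.shape[0]
    ordered = np.sort(stack, axis=0)
    reference = ordered[(b - 1) // 2]
    spread = np.median(np.abs(stack - reference), axis=0)
    return BackgroundModel(reference=reference, spread=spread, frame_count=b)


class ForegroundExtractor(Protocol):
    """Pluggable motion-segmentation interface."""

    def __call__(self, frame: DepthFrame, model: BackgroundModel) -> np.ndarray: ...


def extract_foreground(
    frame: DepthFrame,
    model: BackgroundModel,
    threshold: float = 15.0,
    spread_factor: float = 2.5,
) -> np.ndarray:
    """Threshold depth deviation from the background model.

    A pixel is foreground iff ``|depth - reference| > max(threshold,
    spread_factor * spread)``; the per-pixel spread term absorbs sensor
    flicker where the background itself is noisy.
    """
    if frame.pixels.shape != model.shape:
        raise ValueError(
            f"frame shape {frame.pixels.shape} != model shape {model.shape}"
        )
    tau = np.maximum(threshold, spread_factor * model.spread)
    mask = np.abs(frame.pixels.astype(np.float64) - model.reference) > tau
    return mask.astype(np.uint8)


def denoise_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological opening then closing with a (2r+1)-square element.

    ``radius=0`` is the identity. Opening clears isolated speckle;
    closing fills pinholes inside the silhouette.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return mask.copy()
    footprint = morphology.footprint_rectangle((2 * radius + 1, 2 * radius + 1))
    # mode="min": pixels beyond the border count as background
    opened = morphology.opening(mask.astype(bool), footprint, mode="min")
    closed = morphology.closing(opened, footprint, mode="min")
    return closed.astype(np.uint8)


def masked_depth(mask: np.ndarray, frame: DepthFrame | np.ndarray) -> np.ndarray:
    """AND the binary mask with the depth image: depth on-mask, 0 off-mask."""
    pixels = frame.pixels if isinstance(frame, DepthFrame) else np.asarray(frame)
    if mask.shape != pixels.shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {pixels.shape}")
    return np.where(mask.astype(bool), pixels, 0).astype(pixels.dtype)


def _largest_component(mask: np.ndarray) -> tuple[tuple[int, int, int, int], np.ndarray]:
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoSubjectError("empty foreground mask")
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    best = int(np.argmax(areas)) + 1  # argmax keeps the first (scan-order) max
    component = labeled == best
    ys, xs = np.nonzero(component)
    x, y = int(xs.min()), int(ys.min())
    bbox = (x, y, int(xs.max()) - x + 1, int(ys.max()) - y + 1)
    return bbox, component


def locate_blob(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight bounding box (x, y, w, h) of the largest connected component.

    8-connectivity; area ties break to the topmost-then-leftmost
    component (scan order of the first pixel). Raises
    :class:`NoSubjectError` on an empty mask.
    """
    return _largest_component(mask)[0]


def _tighten(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise NoSubjectError("mask emptied during tightening")
    return int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)


@dataclass(frozen=True)
class HumanBlob:
    """Located subject: bounding box, cropped mask, masked depth profile.

    ``raw_bbox`` is the box before arm rejection, ``bbox`` the final one;
    both are (x, y, w, h) in frame coordinates. ``mask`` and
    ``depth_profile`` are cropped to ``bbox``; the profile is 0 exactly
    where the mask is 0.
    """

    raw_bbox: tuple[int, int, int, int]
    bbox: tuple[int, int, int, int]
    mask: np.ndarray           # uint8, (h, w), values {0,1}
    depth_profile: np.ndarray  # uint8, (h, w), 0 off-mask
    view_id: str = "view0"
    frame_index: int = 0

    @property
    def width(self) -> int:
        return self.bbox[2]

    @property
    def height(self) -> int:
        return self.bbox[3]


def extract_blob(
    frame: DepthFrame,
    model: BackgroundModel,
    threshold: float = 15.0,
    denoise_radius: int = 1,
    arm_strength: float = 0.05,
    extractor: Optional[ForegroundExtractor] = None,
    external_mask: Optional[np.ndarray] = None,
) -> HumanBlob:
    """Run the full per-frame extraction chain and return the subject blob.

    ``external_mask`` (a full-frame 0/1 or 0/255 array) bypasses
    background subtraction entirely, supporting datasets segmented by
    other means.
    """
    if external_mask is not None:
        mask = (np.asarray(external_mask) > 0).astype(np.uint8)
        if mask.shape != frame.pixels.shape:
            raise ValueError("external mask shape mismatch")
    elif extractor is not None:
        mask = np.asarray(extractor(frame, model)).astype(np.uint8)
    else:
        mask = extract_foreground(frame, model, threshold=threshold)
    mask = denoise_mask(mask, radius=denoise_radius)
    raw_bbox, component = _largest_component(mask)
    x, y, w, h = raw_bbox
    crop_mask = component[y:y + h, x:x + w].astype(np.uint8)
    crop_depth = masked_depth(crop_mask, frame.pixels[y:y + h, x:x + w])

    blob = HumanBlob(
        raw_bbox=raw_bbox, bbox=raw_bbox, mask=crop_mask,
        depth_profile=crop_depth, view_id=frame.view_id,
        frame_index=frame.frame_index,
    )
    return remove_arms(blob, strength=arm_strength)


def remove_arms(blob: HumanBlob, strength: float = 0.05) -> HumanBlob:
    """Strip thin protruding limbs so only the torso profile remains.

    Opens the blob mask with a square element of side
    ``max(1, round(strength * H_h))``, then re-tightens the box and
    re-masks the depth profile. ``strength=0`` disables the step. The
    mask is never enlarged; a blob thinner than the element everywhere
    raises :class:`NoSubjectError`.
    """
    if strength == 0:
        return blob
    side = max(1, round(strength * blob.height))
    if side <= 1:
        return blob
    footprint = morphology.footprint_rectangle((side, side))
    opened = morphology.opening(blob.mask.astype(bool), footprint, mode="min")
    if not opened.any():
        raise NoSubjectError("arm-rejection opening removed the whole blob")
    dx, dy, w, h = _tighten(opened.astype(np.uint8))
    x0, y0 = blob.bbox[0] + dx, blob.bbox[1] + dy
    new_mask = opened[dy:dy + h, dx:dx + w].astype(np.uint8)
    new_depth = masked_depth(new_mask, blob.depth_profile[dy:dy + h, dx:dx + w])
    return HumanBlob(
        raw_bbox=blob.raw_bbox, bbox=(x0, y0, w, h), mask=new_mask,
        depth_profile=new_depth, view_id=blob.view_id,
        frame_index=blob.frame_index,
    )
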