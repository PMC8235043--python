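"""Attention detection by matching fixations to detected objects (the *OD* method).

For each fixation the video frame closest to the fixation start is passed
to a pluggable object-detection backend.  Detected instances whose label is
mapped to an AOI are hit-tested against the fixation centroid, either by
their rectangular bounding box (``bbox``, the default) or by their
segmentation mask (``mask``).  A hit emits one attention event spanning
exactly the fixation interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Optional, Protocol, Sequence, Union

import numpy as np

from .core import AttentionEvent, FixationEvent, Region, VideoMeta, point_in_region

__all__ = [
    "DetectedInstance",
    "ODConfig",
    "DetectorBackend",
    "ScriptedDetectorBackend",
    "frame_for_fixation",
    "hit_test",
    "run_od",
]

logger = logging.getLogger(__name__)

Mask = Union[Region, np.ndarray]


@dataclass(frozen=True)
class DetectedInstance:
    """One detected object instance on a single frame.

    ``mask`` may be a polygon :class:`Region` or a full-frame boolean bitmap
    (H x W); it should lie within ``bbox``.  ``mask=None`` means the
    detector provided no segmentation; such instances fall back to their
    bounding box in mask mode.
    """

    label: str
    probability: float
    bbox: Region
    mask: Optional[Mask] = None

    def __post_init__(self) -> None:
        if self.bbox.kind != "rectangle":
            raise ValueError("bbox must be a rectangle region")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability out of [0,1]: {self.probability}")

    def contains(self, x: float, y: float, use_mask: bool) -> bool:
        if not use_mask or self.mask is None:
            return point_in_region(x, y, self.bbox)
        if isinstance(self.mask, Region):
            return point_in_region(x, y, self.mask)
        h, w = self.mask.shape
        xi, yi = int(x), int(y)
        return 0 <= xi < w and 0 <= yi < h and bool(self.mask[yi, xi])


@dataclass(frozen=True)
class ODConfig:
    """Parameters of the OD method (``OD-bbox`` by default)."""

    object_mask: str = "bbox"
    score_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.object_mask not in ("bbox", "mask"):
            raise ValueError("object_mask must be 'bbox' or 'mask'")

    @property
    def name(self) -> str:
        return f"OD-{self.object_mask}"


class DetectorBackend(Protocol):
    def detect(self, frame_index: int) -> Sequence[DetectedInstance]:
        """All object instances detected on a frame."""
        ...


class ScriptedDetectorBackend:
    """Deterministic backend replaying pre-scripted per-frame detections."""

    def __init__(self, detections: Mapping[int, Sequence[DetectedInstance]]) -> None:
        self._detections = {int(k): list(v) for k, v in detections.items()}

    def detect(self, frame_index: int) -> Sequence[DetectedInstance]:
        return self._detections.get(frame_index, [])


def frame_for_fixation(fix: FixationEvent, meta: VideoMeta) -> int:
    """Index of the frame whose timestamp is nearest the fixation start.

    Equidistant ties resolve to the earlier frame.
    """
    if fix.start < 0 or fix.start >= meta.duration:
        raise ValueError(f"fixation start {fix.start} outside video [0, {meta.duration})")
    ft = meta.frame_duration
    lo = int(fix.start // ft)
    hi = lo + 1
    if hi < meta.n_frames and (hi * ft - fix.start) < (fix.start - lo * ft):
        return hi
    return min(lo, meta.n_frames - 1)


def hit_test(
    x: float, y: float, instances: Sequence[DetectedInstance], config: ODConfig
) -> Optional[DetectedInstance]:
    """The instance whose area contains ``(x, y)``, or ``None``.

    Among multiple hits the one with the highest probability wins; exact
    probability ties resolve to the first in input order.
    """
    use_mask = config.object_mask == "mask"
    best: Optional[DetectedInstance] = None
    for inst in instances:
        if inst.contains(x, y, use_mask) and (best is None or inst.probability > best.probability):
            best = inst
    return best


def run_od(
    fixations: Sequence[FixationEvent],
    backend: DetectorBackend,
    aoi_map: Mapping[str, str],
    config: ODConfig,
    meta: VideoMeta,
) -> List[AttentionEvent]:
    """Map each fixation to at most one AOI attention event.

    Instances below the score threshold or with labels absent from
    ``aoi_map`` are excluded before the hit test.  A hit emits an event
    spanning exactly ``[fix.start, fix.end)`` with the mapped AOI name and
    the instance probability.  Backend failures skip the fixation.
    """
    events: List[AttentionEvent] = []
    for fix in fixations:
        try:
            frame = frame_for_fixation(fix, meta)
            instances = backend.detect(frame)
        except Exception:  # noqa: BLE001 - backend is third-party code
            logger.exception("detector failed for fixation at %.1f ms; skipped", fix.start)
            continue
        usable = [
            inst
            for inst in instances
            if inst.probability >= config.score_threshold and inst.label in aoi_map
        ]
        hit = hit_test(fix.x, fix.y, usable, config)
        if hit is not None:
            events.append(
                AttentionEvent(
                    aoi=aoi_map[hit.label],
                    label=hit.label,
                    start=fix.start,
                    end=fix.end,
                    probability=hit.probability,
                    source="OD",
                )
            )
    return events
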