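"""Shared domain types, time/geometry conventions and keyframed AOI regions.

Conventions used throughout the package:

* Time is real-valued milliseconds from recording start; all intervals are
  half-open ``[start, end)``.
* Pixel coordinates have their origin at the top-left corner, x pointing
  right and y pointing down.  Frame indices are 0-based.
* An AOI is considered absent (off screen) outside the span of its
  keyframes; no extrapolation is performed.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple

__all__ = [
    "GazeSample",
    "FixationEvent",
    "VideoMeta",
    "Region",
    "AOITrack",
    "AttentionEvent",
    "TrackInterpolationError",
    "interpolate_track",
    "point_in_region",
    "frame_timestamp",
]

Vertex = Tuple[float, float]


class TrackInterpolationError(ValueError):
    """Raised when a track cannot be interpolated (e.g. vertex-count mismatch)."""


@dataclass(frozen=True)
class GazeSample:
    """A single timed gaze point in video pixel coordinates."""

    timestamp: float
    x: float
    y: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"negative timestamp: {self.timestamp}")


@dataclass(frozen=True)
class FixationEvent:
    """A fixation interval ``[start, end)`` with its pixel centroid."""

    start: float
    end: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"fixation end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class VideoMeta:
    """Static properties of one (egocentric) video timeline."""

    width: int
    height: int
    fps: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_frames < 0:
            raise ValueError("n_frames must be non-negative")

    @property
    def frame_duration(self) -> float:
        """Duration of one frame in milliseconds (``1000 / fps``)."""
        return 1000.0 / self.fps

    @property
    def duration(self) -> float:
        """Total video duration in milliseconds."""
        return self.n_frames * self.frame_duration


@dataclass(frozen=True)
class Region:
    """An axis-aligned rectangle or a simple polygon in pixel coordinates.

    Rectangles are stored as two corner vertices ``(x1, y1), (x2, y2)`` with
    ``x1 < x2`` and ``y1 < y2``.  Polygons are stored as a closed ring of at
    least three vertices (the closing edge is implicit).
    """

    kind: str
    vertices: Tuple[Vertex, ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if self.kind == "rectangle":
            if len(verts) != 2:
                raise ValueError("rectangle needs exactly 2 corner vertices")
            (x1, y1), (x2, y2) = verts
            if not (x1 < x2 and y1 < y2):
                raise ValueError("rectangle corners must satisfy x1<x2, y1<y2")
        elif self.kind == "polygon":
            if len(verts) < 3:
                raise ValueError("polygon needs at least 3 vertices")
        else:
            raise ValueError(f"unknown region kind: {self.kind!r}")

    @classmethod
    def rectangle(cls, x1: float, y1: float, x2: float, y2: float) -> "Region":
        return cls("rectangle", ((x1, y1), (x2, y2)))

    @classmethod
    def polygon(cls, vertices: Sequence[Vertex]) -> "Region":
        return cls("polygon", tuple(vertices))

    @property
    def centroid(self) -> Vertex:
        """Vertex mean for polygons; box center for rectangles."""
        if self.kind == "rectangle":
            (x1, y1), (x2, y2) = self.vertices
            return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return (sum(xs) / len(xs), sum(ys) / len(ys))


@dataclass(frozen=True)
class AOITrack:
    """A keyframed region track for one AOI within one video."""

    aoi_name: str
    keyframes: Tuple[Tuple[int, Region], ...]

    def __post_init__(self) -> None:
        kfs = tuple((int(f), r) for f, r in self.keyframes)
        object.__setattr__(self, "keyframes", kfs)
        frames = [f for f, _ in kfs]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("keyframe frame indices must be strictly increasing")
        kinds = {r.kind for _, r in kfs}
        if len(kinds) > 1:
            raise ValueError("all keyframes of a track must share the region kind")


#: Allowed provenance tags for attention events.
EVENT_SOURCES = ("IC", "OD", "ground_truth")


@dataclass(frozen=True)
class AttentionEvent:
    """A detected or ground-truth attention interval ``[start, end)`` for one AOI.

    ``aoi`` is ``None`` for detections whose raw label has no AOI mapping;
    such events are retained so insertions can be audited.
    """

    aoi: Optional[str]
    label: str
    start: float
    end: float
    probability: float = 1.0
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"event end ({self.end}) must exceed start ({self.start})")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability out of [0,1]: {self.probability}")
        if self.source not in EVENT_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


def interpolate_track(track: AOITrack, frame: int) -> Optional[Region]:
    """Return the track's region at ``frame``, or ``None`` when off screen.

    Exact at keyframes; vertex-wise linear in between; ``None`` outside the
    keyframe span (no extrapolation).

    Raises
    ------
    TrackInterpolationError
        If consecutive polygon keyframes have differing vertex counts.
    """
    kfs = track.keyframes
    if not kfs:
        return None
    frames = [f for f, _ in kfs]
    if frame < frames[0] or frame > frames[-1]:
        return None
    i = bisect_right(frames, frame) - 1
    f0, r0 = kfs[i]
    if f0 == frame:
        return r0
    f1, r1 = kfs[i + 1]
    if len(r0.vertices) != len(r1.vertices):
        raise TrackInterpolationError(
            f"track {track.aoi_name!r}: vertex count mismatch between "
            f"keyframes {f0} ({len(r0.vertices)}) and {f1} ({len(r1.vertices)})"
        )
    t = (frame - f0) / (f1 - f0)
    verts = tuple(
        (ax + t * (bx - ax), ay + t * (by - ay))
        for (ax, ay), (bx, by) in zip(r0.vertices, r1.vertices)
    )
    return Region(r0.kind, verts)


def _on_segment(x: float, y: float, ax: float, ay: float, bx: float, by: float) -> bool:
    cross = (bx - ax) * (y - ay) - (by - ay) * (x - ax)
    if abs(cross) > 1e-9 * max(1.0, abs(bx - ax) + abs(by - ay)):
        return False
    return min(ax, bx) - 1e-12 <= x <= max(ax, bx) + 1e-12 and (
        min(ay, by) - 1e-12 <= y <= max(ay, by) + 1e-12
    )


def point_in_region(x: float, y: float, region: Region) -> bool:
    """Point containment test.

    Rectangles are half-open: ``x1 <= x < x2 and y1 <= y < y2`` (so shared
    edges of adjacent boxes never double-count a point).  Polygons use the
    even-odd rule with the boundary counting as inside.
    """
    if region.kind == "rectangle":
        (x1, y1), (x2, y2) = region.vertices
        return x1 <= x < x2 and y1 <= y < y2
    verts = region.vertices
    n = len(verts)
    # boundary counts as inside
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if _on_segment(x, y, ax, ay, bx, by):
            return True
    inside = False
    j = n - 1
    for i in range(n):
        xi, yi = verts[i]
        xj, yj = verts[j]
        if (yi > y) != (yj > y):
            x_cross = (xj - xi) * (y - yi) / (yj - yi) + xi
            if x < x_cross:
                inside = not inside
        j = i
    return inside


def frame_timestamp(frame: int, meta: VideoMeta) -> float:
    """Timestamp (ms) of a frame's start: ``frame * 1000 / fps``."""
    if not 0 <= frame < meta.n_frames:
        raise ValueError(f"frame {frame} out of range [0, {meta.n_frames})")
    return frame * meta.frame_duration


def frames_spanned(start: float, end: float, meta: VideoMeta) -> Iterator[int]:
    """Frame indices whose display interval overlaps ``[start, end)`` (clipped)."""
    ft = meta.frame_duration
    first = max(0, int(start // ft))
    frame = first
    while frame < meta.n_frames and frame * ft < end:
        if (frame + 1) * ft > start:
            yield frame
        frame += 1
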