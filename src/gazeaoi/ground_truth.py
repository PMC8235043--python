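"""Ground-truth attention events from fixations and annotated AOI tracks.

A fixation contributes a positive frame to an AOI when its centroid lies
inside the AOI's (keyframe-interpolated) region on that frame.  Hit testing
is frame-wise across every frame the fixation spans.  Contiguous positive
frames per AOI become ground-truth events aligned to frame boundaries.

When two or more AOIs claim the same frame, the conflict is resolved per
contiguous run of identically-claimed frames: the run goes to the AOI whose
candidate contiguous event (measured before resolution) is longer, ties to
the AOI first in track order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .core import (
    AOITrack,
    AttentionEvent,
    FixationEvent,
    VideoMeta,
    frames_spanned,
    interpolate_track,
    point_in_region,
)

__all__ = ["GroundTruthSet", "extract_ground_truth"]


@dataclass
class GroundTruthSet:
    """Per-AOI ground-truth attention events on one video timeline."""

    events_by_aoi: Dict[str, List[AttentionEvent]] = field(default_factory=dict)
    timeline: VideoMeta | None = None

    @property
    def all_events(self) -> List[AttentionEvent]:
        out = [e for events in self.events_by_aoi.values() for e in events]
        out.sort(key=lambda e: (e.start, e.end, e.aoi or ""))
        return out


def _runs(signal: np.ndarray) -> List[tuple[int, int]]:
    """Half-open ``(start, end)`` frame runs where ``signal`` is true."""
    idx = np.flatnonzero(signal)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def _run_length_at(signal: np.ndarray, frame: int) -> int:
    """Length of the contiguous positive run of ``signal`` containing ``frame``."""
    lo = frame
    while lo > 0 and signal[lo - 1]:
        lo -= 1
    hi = frame + 1
    while hi < signal.size and signal[hi]:
        hi += 1
    return hi - lo


def extract_ground_truth(
    fixations: Sequence[FixationEvent],
    tracks: Sequence[AOITrack],
    meta: VideoMeta,
) -> GroundTruthSet:
    """Extract per-AOI ground-truth events (see module docstring).

    The result is invariant to the ordering of ``fixations``; per frame the
    assignment is binary and conflict-free across AOIs.
    """
    aoi_order = [t.aoi_name for t in tracks]
    hits: Dict[str, np.ndarray] = {name: np.zeros(meta.n_frames, dtype=bool) for name in aoi_order}

    for fix in fixations:
        for frame in frames_spanned(fix.start, fix.end, meta):
            for track in tracks:
                region = interpolate_track(track, frame)
                if region is not None and point_in_region(fix.x, fix.y, region):
                    hits[track.aoi_name][frame] = True

    # conflict resolution: runs of frames with an identical (>=2) claim set;
    # candidate-event lengths are measured on the unresolved hit arrays
    if len(aoi_order) >= 2:
        original = {name: hits[name].copy() for name in aoi_order}
        claim = np.stack([hits[name] for name in aoi_order])  # (n_aoi, n_frames)
        multi = claim.sum(axis=0) >= 2
        frame = 0
        while frame < meta.n_frames:
            if not multi[frame]:
                frame += 1
                continue
            key = claim[:, frame].copy()
            end = frame
            while end < meta.n_frames and multi[end] and np.array_equal(claim[:, end], key):
                end += 1
            contenders = [i for i in range(len(aoi_order)) if key[i]]
            winner = max(
                contenders,
                key=lambda i: (_run_length_at(original[aoi_order[i]], frame), -i),
            )
            for i in contenders:
                if i != winner:
                    hits[aoi_order[i]][frame:end] = False
            frame = end

    ft = meta.frame_duration
    events_by_aoi: Dict[str, List[AttentionEvent]] = {}
    for name in aoi_order:
        events = [
            AttentionEvent(
                aoi=name,
                label=name,
                start=s * ft,
                end=e * ft,
                probability=1.0,
                source="ground_truth",
            )
            for s, e in _runs(hits[name])
        ]
        if events:
            events_by_aoi[name] = events
    return GroundTruthSet(events_by_aoi=events_by_aoi, timeline=meta)
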