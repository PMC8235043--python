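"""Synthetic fixtures: ground-truth scenarios, error-injected prediction
streams with exact expected error ledgers, noisy gaze traces, and scripted
vision backends.

Everything here is deterministic under an explicit seed (one
``numpy.random.Generator`` per call, no global state).  Perturbations are
constrained to non-interacting, well-separated edits so the expected event
error counts are exact; infeasible or conflicting specs raise instead of
silently producing a mislabeled ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    AOITrack,
    AttentionEvent,
    FixationEvent,
    GazeSample,
    VideoMeta,
    interpolate_track,
)
from .evaluation import EventErrorCounts
from .ic import ClassPrediction

__all__ = [
    "PerturbationSpec",
    "gen_gt_events",
    "perturb_events",
    "mock_classifier",
    "gen_gaze",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled error injection for a ground-truth event stream.

    ``fragmentations`` lists ``(event_index, parts)`` splits and ``merges``
    lists ``(first_event_index, span)`` bridges over consecutive events.
    ``jitter_start`` / ``jitter_end`` shift the boundaries of otherwise
    untouched events (overfill when negative start / positive end jitter).
    All targets must be distinct.
    """

    n_delete: int = 0
    n_insert: int = 0
    fragmentations: Tuple[Tuple[int, int], ...] = ()
    merges: Tuple[Tuple[int, int], ...] = ()
    jitter_start: float = 0.0
    jitter_end: float = 0.0


def gen_gt_events(
    n: int,
    duration_range: Tuple[float, float],
    gap_range: Tuple[float, float],
    seed: int,
    frame_time: float = 40.0,
    aoi: str = "aoi",
    label: Optional[str] = None,
    start: float = 0.0,
) -> List[AttentionEvent]:
    """``n`` disjoint, ordered, frame-aligned ground-truth events.

    Durations and gaps are drawn uniformly (in whole frames) from the given
    millisecond ranges.  The minimum gap must exceed two frame times so
    events stay well separated after any frame-level processing.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    d_lo, d_hi = duration_range
    g_lo, g_hi = gap_range
    if g_lo <= 2 * frame_time:
        raise ValueError("minimum gap must exceed two frame times")
    if d_lo < frame_time or d_hi < d_lo or g_hi < g_lo:
        raise ValueError("infeasible duration/gap ranges")
    rng = np.random.default_rng(seed)
    d_frames = (max(1, round(d_lo / frame_time)), max(1, int(d_hi // frame_time)))
    g_frames = (int(g_lo // frame_time) + 1, max(int(g_lo // frame_time) + 1, int(g_hi // frame_time)))
    if d_frames[1] < d_frames[0]:
        raise ValueError("duration range narrower than one frame")
    events: List[AttentionEvent] = []
    t = start
    for i in range(n):
        dur = int(rng.integers(d_frames[0], d_frames[1] + 1)) * frame_time
        events.append(
            AttentionEvent(
                aoi=aoi,
                label=label if label is not None else aoi,
                start=t,
                end=t + dur,
                probability=1.0,
                source="ground_truth",
            )
        )
        gap = int(rng.integers(g_frames[0], g_frames[1] + 1)) * frame_time
        t += dur + gap
    return events


def _frames(ms: float, frame_time: float) -> int:
    return int(round(ms / frame_time))


def perturb_events(
    gt: Sequence[AttentionEvent],
    spec: PerturbationSpec,
    seed: int,
    frame_time: float = 40.0,
) -> Tuple[List[AttentionEvent], EventErrorCounts]:
    """Apply a :class:`PerturbationSpec` and return the exact expected ledger.

    Deletions drop randomly chosen untouched events; insertions place
    one-frame events in the middle of sufficiently wide gaps;
    fragmentations split an event into parts separated by one-frame gaps;
    merges bridge runs of consecutive events.  Remaining events are copied
    (optionally boundary-jittered) and stay correct.  The returned
    :class:`EventErrorCounts` is guaranteed to equal the scoring result of
    the perturbed stream against ``gt``.
    """
    gt = sorted(gt, key=lambda e: e.start)
    n = len(gt)
    rng = np.random.default_rng(seed)

    targeted: set[int] = set()

    def claim(indices: Sequence[int], what: str) -> None:
        for i in indices:
            if i < 0 or i >= n:
                raise ValueError(f"{what}: event index {i} out of range")
            if i in targeted:
                raise ValueError(f"{what}: event {i} targeted twice")
            targeted.add(i)

    for idx, parts in spec.fragmentations:
        if parts < 2:
            raise ValueError("fragmentation needs >= 2 parts")
        claim([idx], "fragmentation")
        if _frames(gt[idx].duration, frame_time) < 2 * parts - 1:
            raise ValueError(f"event {idx} too short to fragment into {parts} parts")
    for idx, span in spec.merges:
        if span < 2:
            raise ValueError("merge needs span >= 2")
        claim(range(idx, idx + span), "merge")

    free = [i for i in range(n) if i not in targeted]
    if spec.n_delete > len(free):
        raise ValueError("not enough untouched events to delete")
    deleted = set(
        int(i) for i in rng.choice(free, size=spec.n_delete, replace=False)
    ) if spec.n_delete else set()

    pred: List[AttentionEvent] = []

    def mk(start: float, end: float, src_label: str = "pred") -> AttentionEvent:
        return AttentionEvent(
            aoi=gt[0].aoi if gt else "aoi",
            label=src_label,
            start=start,
            end=end,
            probability=1.0,
            source="ground_truth",
        )

    frag_by_idx = dict(spec.fragmentations)
    merge_starts = {idx: span for idx, span in spec.merges}
    jitter_s = _frames(spec.jitter_start, frame_time) * frame_time
    jitter_e = _frames(spec.jitter_end, frame_time) * frame_time

    expected = EventErrorCounts()
    i = 0
    while i < n:
        e = gt[i]
        if i in deleted:
            expected.D += 1
            i += 1
        elif i in frag_by_idx:
            parts = frag_by_idx[i]
            L = _frames(e.duration, frame_time)
            base = (L - (parts - 1)) // parts
            extra = (L - (parts - 1)) % parts
            cursor = e.start
            for p in range(parts):
                length = (base + (1 if p < extra else 0)) * frame_time
                pred.append(mk(cursor, cursor + length))
                cursor += length + frame_time  # one-frame gap
            expected.F += 1
            expected.F_prime += parts
            i += 1
        elif i in merge_starts:
            span = merge_starts[i]
            if i + span > n:
                raise ValueError("merge span exceeds stream length")
            pred.append(mk(gt[i].start, gt[i + span - 1].end))
            expected.M += span
            expected.M_prime += 1
            i += span
        else:
            start = e.start + jitter_s
            end = e.end + jitter_e
            # keep the jittered copy overlapping its source and clear of neighbours
            prev_end = gt[i - 1].end if i > 0 else -np.inf
            next_start = gt[i + 1].start if i + 1 < n else np.inf
            if not (start < end and end > e.start and start < e.end):
                raise ValueError("jitter destroys the event's overlap with itself")
            if start <= prev_end or end >= next_start:
                raise ValueError("jitter makes an event interact with a neighbour")
            pred.append(mk(start, end))
            expected.C += 1
            i += 1

    # insertions: one-frame events centred in gaps wide enough to stay clear
    if spec.n_insert:
        bridged = {
            j for idx, span in spec.merges for j in range(idx, idx + span - 1)
        }  # gap after event j is filled by a merging prediction
        gaps: List[Tuple[float, float]] = []
        for j, (a, b) in enumerate(zip(gt, gt[1:])):
            if j in bridged:
                continue
            lo = max(a.end, a.end + jitter_e) + frame_time
            hi = min(b.start, b.start + jitter_s) - frame_time
            if hi - lo >= frame_time:
                gaps.append((lo, hi))
        tail = gt[-1].end + max(jitter_e, 0.0) + frame_time if gt else 0.0
        gaps.append((tail, tail + spec.n_insert * 3 * frame_time))
        slots: List[float] = []
        for lo, hi in gaps:
            lo_f = int(np.ceil(lo / frame_time))
            hi_f = int(np.floor(hi / frame_time)) - 1
            slots.extend(f * frame_time for f in range(lo_f, hi_f + 1, 3))
        if len(slots) < spec.n_insert:
            raise ValueError("not enough room for the requested insertions")
        chosen = rng.choice(len(slots), size=spec.n_insert, replace=False)
        for k in sorted(chosen):
            pred.append(mk(slots[int(k)], slots[int(k)] + frame_time))
        expected.I_prime += spec.n_insert

    pred.sort(key=lambda e: e.start)
    return pred, expected


def mock_classifier(
    gt: Sequence[AttentionEvent],
    tick_rate: float,
    hit_prob: float,
    confusers: Sequence[str],
    p_hit: float,
    seed: int,
    t_end: Optional[float] = None,
) -> List[ClassPrediction]:
    """A scripted top-1 classification stream driven by ground-truth events.

    At every tick inside a ground-truth event the event's label is emitted
    with probability ``hit_prob`` (carrying model confidence ``p_hit``),
    otherwise a confuser label; outside events only confusers are emitted.
    """
    if not 0.0 <= hit_prob <= 1.0 or not 0.0 <= p_hit <= 1.0:
        raise ValueError("probabilities must lie in [0,1]")
    if not confusers:
        raise ValueError("need at least one confuser label")
    rng = np.random.default_rng(seed)
    gt = sorted(gt, key=lambda e: e.start)
    if t_end is None:
        t_end = (gt[-1].end if gt else 0.0) + 1000.0
    spacing = 1000.0 / tick_rate
    stream: List[ClassPrediction] = []
    t = 0.0
    while t <= t_end:
        label = None
        for e in gt:
            if e.start <= t < e.end:
                if rng.random() < hit_prob:
                    label = e.label
                break
        if label is None:
            label = str(confusers[int(rng.integers(len(confusers)))])
        stream.append(ClassPrediction(label, p_hit, t))
        t += spacing
    return stream


def gen_gaze(
    gt: Sequence[AttentionEvent],
    tracks: Sequence[AOITrack],
    meta: VideoMeta,
    sigma: float,
    rate: float,
    seed: int,
) -> Tuple[List[GazeSample], List[FixationEvent]]:
    """Gaze samples and fixations around AOI centroids during events.

    During each ground-truth event, gaze samples at ``rate`` Hz sit on the
    event AOI's interpolated region centroid plus isotropic Gaussian noise
    of scale ``sigma`` (modelling limited spatial accuracy).  One fixation
    per event is emitted whose centroid is the mean of the event's samples.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    by_name: Dict[str, AOITrack] = {t.aoi_name: t for t in tracks}
    spacing = 1000.0 / rate
    samples: List[GazeSample] = []
    fixations: List[FixationEvent] = []
    for e in sorted(gt, key=lambda ev: ev.start):
        track = by_name.get(e.aoi or "")
        if track is None:
            continue
        pts: List[Tuple[float, float]] = []
        t = e.start
        while t < e.end:
            frame = min(int(t // meta.frame_duration), meta.n_frames - 1)
            region = interpolate_track(track, frame)
            if region is not None:
                cx, cy = region.centroid
                noise = rng.normal(0.0, sigma, size=2) if sigma > 0 else np.zeros(2)
                x, y = cx + noise[0], cy + noise[1]
                samples.append(GazeSample(t, x, y, True))
                pts.append((x, y))
            t += spacing
        if pts:
            fx = float(np.mean([p[0] for p in pts]))
            fy = float(np.mean([p[1] for p in pts]))
            fixations.append(FixationEvent(e.start, e.end, fx, fy))
    return samples, fixations
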