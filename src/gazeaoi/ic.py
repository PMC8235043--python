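"""Attention detection from gaze-guided image-patch classification (the *IC* method).

The pipeline has four stages: the gaze signal is resampled to a low, fixed
rate (default 5 Hz); a square patch (default 200x200 px) is cropped around
each remaining sample and classified by a pluggable backend that returns
top-5 ``(label, probability)`` candidates; similar labels are merged by
summing their probabilities via a lookup table; and the resulting top-1
stream drives a working-memory, threshold-based event machine with a
per-label duration counter and noise counter.

The event machine emits *started* / *confirmed* / *ended* signals.  Signal
timestamps are corrected by subtracting the duration threshold so that they
better match the actual attention onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Protocol, Sequence, Tuple

from .core import AttentionEvent, GazeSample, VideoMeta

__all__ = [
    "ClassPrediction",
    "LabelMergeMap",
    "ICConfig",
    "ICState",
    "AttentionSignal",
    "ClassifierBackend",
    "PatchRequest",
    "ScriptedClassifierBackend",
    "resample_gaze",
    "crop_geometry",
    "merge_labels",
    "update_attention",
    "signals_to_events",
    "run_ic",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassPrediction:
    """A top-1 class candidate ``(c, p(c))`` at a point in time."""

    label: str
    probability: float
    timestamp: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability out of [0,1]: {self.probability}")


class LabelMergeMap:
    """Lookup table mapping class labels to a canonical (merged) label.

    Labels absent from the table are their own canonical label; canonical
    labels always map to themselves.
    """

    def __init__(self, mapping: Optional[Mapping[str, str]] = None) -> None:
        self._map: Dict[str, str] = {}
        for label, canonical in (mapping or {}).items():
            self._map[label] = canonical
            self._map.setdefault(canonical, canonical)
        for label, canonical in self._map.items():
            if self._map.get(canonical, canonical) != canonical:
                raise ValueError(f"canonical label {canonical!r} must map to itself")

    def canonical(self, label: str) -> str:
        return self._map.get(label, label)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_groups(cls, groups: Sequence[Sequence[str]]) -> "LabelMergeMap":
        """Build a map from label groups; the first member is canonical."""
        mapping: Dict[str, str] = {}
        for group in groups:
            if not group:
                continue
            head = group[0]
            for label in group:
                mapping[label] = head
        return cls(mapping)


@dataclass(frozen=True)
class ICConfig:
    """Parameters of the IC method.

    Defaults correspond to the setting named ``IC-152-300-40``:
    ``t_dur = t_noise = 300 ms``, ``t_prob = 0.40``, ResNet-152 backend,
    5 Hz resampling and a 200 px patch.
    """

    t_dur: float = 300.0
    t_noise: float = 300.0
    t_prob: float = 0.40
    model_name: str = "152"
    sample_rate: float = 5.0
    patch_size: int = 200

    def __post_init__(self) -> None:
        if self.t_dur <= 0 or self.t_noise <= 0:
            raise ValueError("t_dur and t_noise must be positive")
        if not 0.0 <= self.t_prob <= 1.0:
            raise ValueError("t_prob must lie in [0,1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def name(self) -> str:
        """Parameterized method name, e.g. ``IC-152-300-40``."""
        return f"IC-{self.model_name}-{self.t_dur:g}-{round(self.t_prob * 100):d}"


@dataclass
class ICState:
    """Mutable working memory of the attention event machine."""

    c_dur: Dict[str, float] = field(default_factory=dict)
    c_noise: Dict[str, float] = field(default_factory=dict)
    c_active: Optional[str] = None
    last_update: Optional[float] = None


@dataclass(frozen=True)
class AttentionSignal:
    kind: str  # started | confirmed | ended
    label: str
    probability: float
    timestamp: float

    def __post_init__(self) -> None:
        if self.kind not in ("started", "confirmed", "ended"):
            raise ValueError(f"unknown signal kind {self.kind!r}")


@dataclass(frozen=True)
class PatchRequest:
    """What a classifier backend gets to look at for one tick."""

    timestamp: float
    x: float
    y: float
    frame_index: Optional[int] = None
    patch: Optional[object] = None  # HxWx3 array when a frame provider is wired in


class ClassifierBackend(Protocol):
    def top5(self, request: PatchRequest) -> Sequence[Tuple[str, float]]:
        """Return up to five ``(label, probability)`` candidates for a patch."""
        ...


class ScriptedClassifierBackend:
    """Deterministic backend replaying a pre-scripted prediction stream.

    For each request it returns the scripted prediction whose timestamp is
    nearest to the request timestamp, as a single-entry top-5 list.  Used by
    tests and offline runs in place of a real CNN.
    """

    def __init__(self, predictions: Sequence[ClassPrediction]) -> None:
        self._preds = sorted(predictions, key=lambda p: p.timestamp)

    def top5(self, request: PatchRequest) -> Sequence[Tuple[str, float]]:
        if not self._preds:
            return []
        best = min(self._preds, key=lambda p: (abs(p.timestamp - request.timestamp), p.timestamp))
        return [(best.label, best.probability)]


def resample_gaze(samples: Sequence[GazeSample], rate: float) -> List[GazeSample]:
    """Downsample a gaze stream to ``rate`` Hz by nearest-sample picking.

    Ticks are spaced ``1000 / rate`` ms starting at the first sample's
    timestamp.  Each tick takes the input sample nearest in time (ties go to
    the earlier sample); ticks with no sample within half a tick are
    dropped, and a sample is never emitted twice.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not samples:
        return []
    spacing = 1000.0 / rate
    times = [s.timestamp for s in samples]
    out: List[GazeSample] = []
    last_idx = -1
    tick = times[0]
    end = times[-1] + spacing / 2.0
    import bisect

    while tick < end:
        i = bisect.bisect_left(times, tick)
        # candidates: times[i-1] (<= tick) and times[i] (>= tick); tie -> earlier
        best = None
        if i > 0:
            best = i - 1
        if i < len(times):
            if best is None or abs(times[i] - tick) < abs(times[best] - tick):
                best = i
        assert best is not None
        if abs(times[best] - tick) <= spacing / 2.0 and best != last_idx:
            out.append(samples[best])
            last_idx = best
        tick += spacing
    return out


def crop_geometry(
    x: float, y: float, patch: int, meta: VideoMeta
) -> Tuple[float, float, float, float]:
    """Patch rectangle ``(x1, y1, x2, y2)`` centered at the gaze point.

    The rectangle is shifted (clamped) to lie fully inside the frame; gaze
    points outside the frame are clamped to the frame first.
    """
    if patch > min(meta.width, meta.height):
        raise ValueError("patch larger than frame")
    x = min(max(x, 0.0), float(meta.width))
    y = min(max(y, 0.0), float(meta.height))
    x1 = min(max(x - patch / 2.0, 0.0), meta.width - patch)
    y1 = min(max(y - patch / 2.0, 0.0), meta.height - patch)
    return (x1, y1, x1 + patch, y1 + patch)


def merge_labels(
    top5: Sequence[Tuple[str, float]], merge_map: LabelMergeMap
) -> List[Tuple[str, float]]:
    """Merge same/similar class labels by accumulating their probabilities.

    Entries sharing a canonical label are replaced by one entry carrying the
    summed probability.  The output is sorted by probability descending
    (stable on ties); its top-1 entry feeds the attention event machine.
    """
    if len(top5) > 5:
        raise ValueError("expected at most 5 candidates")
    acc: Dict[str, float] = {}
    order: List[str] = []
    for label, prob in top5:
        canonical = merge_map.canonical(label)
        if canonical not in acc:
            acc[canonical] = 0.0
            order.append(canonical)
        acc[canonical] += prob
    ranked = sorted(order, key=lambda c: -acc[c])
    return [(c, acc[c]) for c in ranked]


def update_attention(
    state: ICState, pred: ClassPrediction, config: ICConfig
) -> List[AttentionSignal]:
    """Advance the event machine by one prediction; returns emitted signals.

    With ``delta`` the stream time since the previous update (0 on the first
    call):

    1. if ``p(c) > t_prob`` the duration counter of ``c`` grows by
       ``delta`` and the noise counter of every *other* label with a
       non-zero duration count grows by ``delta``; if ``p(c) <= t_prob``
       the tick counts as noise for every label with a non-zero duration
       count (a low-confidence tick supports no label);
    2. if ``c``'s duration counter exceeds ``t_dur`` the previously active
       label (if different) is *ended*, ``c`` is *started* (or *confirmed*
       when already active) and both of ``c``'s counters reset;
    3. any label whose noise counter exceeds ``t_noise`` has both counters
       reset, emitting *ended* if it was the active label.

    All emitted timestamps are ``pred.timestamp - t_dur``.  ``state`` is
    mutated in place.
    """
    if state.last_update is not None and pred.timestamp < state.last_update:
        raise ValueError(
            f"non-monotone prediction timestamp: {pred.timestamp} < {state.last_update}"
        )
    delta = 0.0 if state.last_update is None else pred.timestamp - state.last_update
    state.last_update = pred.timestamp
    c = pred.label
    signals: List[AttentionSignal] = []
    ts = pred.timestamp - config.t_dur

    if pred.probability > config.t_prob:
        state.c_dur[c] = state.c_dur.get(c, 0.0) + delta
        for k, dur in state.c_dur.items():
            if k != c and dur > 0:
                state.c_noise[k] = state.c_noise.get(k, 0.0) + delta
    else:
        for k, dur in state.c_dur.items():
            if dur > 0:
                state.c_noise[k] = state.c_noise.get(k, 0.0) + delta

    if state.c_dur.get(c, 0.0) > config.t_dur:
        if state.c_active is not None and state.c_active != c:
            signals.append(AttentionSignal("ended", state.c_active, pred.probability, ts))
        kind = "confirmed" if state.c_active == c else "started"
        signals.append(AttentionSignal(kind, c, pred.probability, ts))
        state.c_active = c
        state.c_dur[c] = 0.0
        state.c_noise[c] = 0.0

    for k in list(state.c_dur):
        if state.c_noise.get(k, 0.0) > config.t_noise:
            state.c_dur[k] = 0.0
            state.c_noise[k] = 0.0
            if k == state.c_active:
                signals.append(AttentionSignal("ended", k, pred.probability, ts))
                state.c_active = None
    return signals


def signals_to_events(
    signals: Sequence[AttentionSignal], stream_end: Optional[float] = None
) -> List[AttentionEvent]:
    """Pair *started*/*ended* signals of the same label into attention events.

    *confirmed* signals do not alter intervals.  A *started* without a
    matching *ended* is closed at ``stream_end`` (defaulting to the last
    signal timestamp); an *ended* without a *started* is dropped with a
    warning.  Zero-length closures are discarded.
    """
    open_by_label: Dict[str, AttentionSignal] = {}
    events: List[AttentionEvent] = []
    for sig in signals:
        if sig.kind == "started":
            if sig.label in open_by_label:
                logger.warning("started %r while already open; restarting", sig.label)
            open_by_label[sig.label] = sig
        elif sig.kind == "ended":
            start = open_by_label.pop(sig.label, None)
            if start is None:
                logger.warning("ended %r without started; dropped", sig.label)
                continue
            if sig.timestamp > start.timestamp:
                events.append(
                    AttentionEvent(
                        aoi=None,
                        label=sig.label,
                        start=start.timestamp,
                        end=sig.timestamp,
                        probability=start.probability,
                        source="IC",
                    )
                )
    if open_by_label:
        if stream_end is None and signals:
            stream_end = max(s.timestamp for s in signals)
        for label, start in open_by_label.items():
            if stream_end is not None and stream_end > start.timestamp:
                events.append(
                    AttentionEvent(
                        aoi=None,
                        label=label,
                        start=start.timestamp,
                        end=stream_end,
                        probability=start.probability,
                        source="IC",
                    )
                )
    events.sort(key=lambda e: (e.start, e.end, e.label))
    return events


FrameProvider = Callable[[int], Optional[object]]


def run_ic(
    gaze: Sequence[GazeSample],
    backend: ClassifierBackend,
    merge_map: LabelMergeMap,
    aoi_map: Mapping[str, str],
    config: ICConfig,
    meta: VideoMeta,
    frames: Optional[FrameProvider] = None,
) -> List[AttentionEvent]:
    """Run the full IC pipeline on a gaze stream.

    Composition: resample -> crop -> classify -> merge -> event machine ->
    interval pairing.  Event labels are translated to AOI names via
    ``aoi_map``; events with unmapped labels are retained with ``aoi=None``
    so insertions can be audited.  Backend failures skip the tick.
    """
    resampled = resample_gaze([s for s in gaze if s.valid], config.sample_rate)
    state = ICState()
    signals: List[AttentionSignal] = []
    last_ts: Optional[float] = None
    for sample in resampled:
        x1, y1, x2, y2 = crop_geometry(sample.x, sample.y, config.patch_size, meta)
        frame_index = min(int(sample.timestamp // meta.frame_duration), meta.n_frames - 1)
        patch = None
        if frames is not None:
            patch = frames(frame_index)
        request = PatchRequest(sample.timestamp, sample.x, sample.y, frame_index, patch)
        try:
            top5 = backend.top5(request)
        except Exception:  # noqa: BLE001 - backend is third-party code
            logger.exception("backend failed at t=%.1f ms; tick skipped", sample.timestamp)
            continue
        merged = merge_labels(list(top5), merge_map)
        if not merged:
            continue
        label, prob = merged[0]
        pred = ClassPrediction(label, min(prob, 1.0), sample.timestamp)
        signals.extend(update_attention(state, pred, config))
        last_ts = sample.timestamp
    events = signals_to_events(signals, stream_end=last_ts)
    return [
        AttentionEvent(
            aoi=aoi_map.get(e.label),
            label=e.label,
            start=e.start,
            end=e.end,
            probability=e.probability,
            source="IC",
        )
        for e in events
    ]
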