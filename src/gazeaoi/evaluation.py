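"""Segment-based event and frame error taxonomy and metrics.

Ground truth and prediction are compared per AOI (one-vs-rest) as boolean
signals over video frames.  The frame timeline is split into segments, i.e.
maximal runs on which both signals are constant, and every segment is rated
true positive / true negative / false positive / false negative.

Events (maximal positive runs) are classified into error classes:

* ground-truth side: deletion ``D``, fragmented ``F``, merged ``M``, both
  ``FM``, or correct ``C``;
* prediction side: insertion ``I'``, fragmenting ``F'``, merging ``M'``,
  both ``FM'``, or correct ``C``.

``C`` is counted once and is identical from both sides.  The identities
``|E| = D + F + FM + M + C`` and ``|R| = M' + FM' + F' + I' + C`` hold by
construction.

Frames of false segments are classified as insertion/merge/overfill on the
false-positive side and deletion/fragmentation/underfill on the
false-negative side, with ``P = Df + Ff + Uf_a + Uf_w + TP`` and
``N = If + Mf + Of_a + Of_w + TN``.

Ratios (``Pr``, ``Re``, ``Pr*``, ``Re*``, ``f1`` and the frame rates) are
expressed in percent; undefined ratios (zero denominator) are reported as
``None`` rather than 0 or 100 so aggregated tables are not biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import AttentionEvent, VideoMeta

__all__ = [
    "Segment",
    "EventErrorCounts",
    "FrameErrorCounts",
    "MetricRecord",
    "preprocess_events",
    "binarize",
    "segment_signals",
    "events_from_signal",
    "score_events",
    "score_frames",
    "compute_metrics",
    "aggregate",
    "is_failing",
    "render_ead",
    "plot_ead",
    "evaluate_signals",
    "evaluate_streams",
]

Interval = Tuple[int, int]  # half-open frame interval


@dataclass
class Segment:
    """A maximal frame run on which ground truth and prediction are constant."""

    start_frame: int
    end_frame: int
    gt: bool
    pred: bool
    frame_class: Optional[str] = None

    @property
    def rating(self) -> str:
        if self.gt and self.pred:
            return "TP"
        if self.gt:
            return "FN"
        if self.pred:
            return "FP"
        return "TN"

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class EventErrorCounts:
    """Event-level error-class tallies (D, F, FM, M, C; I', F', FM', M')."""

    D: int = 0
    F: int = 0
    FM: int = 0
    M: int = 0
    C: int = 0
    I_prime: int = 0
    F_prime: int = 0
    FM_prime: int = 0
    M_prime: int = 0

    @property
    def E_total(self) -> int:
        """Number of ground-truth events: ``|E| = D + F + FM + M + C``."""
        return self.D + self.F + self.FM + self.M + self.C

    @property
    def R_total(self) -> int:
        """Number of returned events: ``|R| = M' + FM' + F' + I' + C``."""
        return self.M_prime + self.FM_prime + self.F_prime + self.I_prime + self.C

    def __add__(self, other: "EventErrorCounts") -> "EventErrorCounts":
        return EventErrorCounts(
            **{f.name: getattr(self, f.name) + getattr(other, f.name) for f in fields(self)}
        )


@dataclass
class FrameErrorCounts:
    """Frame-level error-class tallies with P/N decompositions."""

    Df: int = 0
    Ff: int = 0
    Uf_alpha: int = 0
    Uf_omega: int = 0
    TP: int = 0
    If: int = 0
    Mf: int = 0
    Of_alpha: int = 0
    Of_omega: int = 0
    TN: int = 0

    @property
    def P(self) -> int:
        return self.Df + self.Ff + self.Uf_alpha + self.Uf_omega + self.TP

    @property
    def N(self) -> int:
        return self.If + self.Mf + self.Of_alpha + self.Of_omega + self.TN

    def __add__(self, other: "FrameErrorCounts") -> "FrameErrorCounts":
        return FrameErrorCounts(
            **{f.name: getattr(self, f.name) + getattr(other, f.name) for f in fields(self)}
        )


@dataclass
class MetricRecord:
    """Event and frame metrics in percent; ``None`` marks undefined ratios."""

    Pr: Optional[float] = None
    Re: Optional[float] = None
    Pr_star: Optional[float] = None
    Re_star: Optional[float] = None
    f1: Optional[float] = None
    dr: Optional[float] = None
    fr: Optional[float] = None
    u_alpha: Optional[float] = None
    u_omega: Optional[float] = None
    tpr: Optional[float] = None
    ir: Optional[float] = None
    mr: Optional[float] = None
    o_alpha: Optional[float] = None
    o_omega: Optional[float] = None
    fpr: Optional[float] = None


# ---------------------------------------------------------------------------
# formula helpers (percent scale)


def conservative_precision(C: int, R_total: int) -> Optional[float]:
    """``Pr = C / |R|`` in percent; ``None`` when ``|R| = 0``."""
    return None if R_total == 0 else 100.0 * C / R_total


def conservative_recall(C: int, E_total: int) -> Optional[float]:
    """``Re = C / |E|`` in percent; ``None`` when ``|E| = 0``."""
    return None if E_total == 0 else 100.0 * C / E_total


def progressive_precision(I_prime: int, R_total: int) -> Optional[float]:
    """``Pr* = (|R| - I') / |R|`` in percent."""
    return None if R_total == 0 else 100.0 * (R_total - I_prime) / R_total


def progressive_recall(D: int, E_total: int) -> Optional[float]:
    """``Re* = (|E| - D) / |E|`` in percent."""
    return None if E_total == 0 else 100.0 * (E_total - D) / E_total


def f1_score(pr_star: Optional[float], re_star: Optional[float]) -> Optional[float]:
    """Event-based ``f1 = 2 Pr* Re* / (Pr* + Re*)`` on the percent scale."""
    if pr_star is None or re_star is None or pr_star + re_star == 0:
        return None
    return 2.0 * pr_star * re_star / (pr_star + re_star)


# ---------------------------------------------------------------------------
# pre-processing and frame projection


def preprocess_events(
    events: Sequence[AttentionEvent], frame_time: float
) -> List[AttentionEvent]:
    """Drop sub-frame events, then merge adjacent same-AOI events.

    Events shorter than one frame time are removed first; afterwards,
    same-AOI events separated by a gap smaller than one frame time are
    merged into one.  Operates per AOI; input must be time-ordered per AOI.
    """
    kept = [e for e in events if e.duration >= frame_time]
    by_aoi: Dict[object, List[AttentionEvent]] = {}
    for e in kept:
        by_aoi.setdefault(e.aoi, []).append(e)
    out: List[AttentionEvent] = []
    for aoi_events in by_aoi.values():
        aoi_events.sort(key=lambda e: e.start)
        current = aoi_events[0]
        for nxt in aoi_events[1:]:
            if nxt.start - current.end < frame_time:
                current = AttentionEvent(
                    aoi=current.aoi,
                    label=current.label,
                    start=current.start,
                    end=max(current.end, nxt.end),
                    probability=max(current.probability, nxt.probability),
                    source=current.source,
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    out.sort(key=lambda e: (e.start, e.end))
    return out


def binarize(events: Sequence[AttentionEvent], timeline: VideoMeta) -> np.ndarray:
    """Boolean per-frame signal: a frame is positive iff its midpoint
    timestamp lies within some event interval."""
    ft = timeline.frame_duration
    mid = (np.arange(timeline.n_frames) + 0.5) * ft
    signal = np.zeros(timeline.n_frames, dtype=bool)
    for e in events:
        signal |= (mid >= e.start) & (mid < e.end)
    return signal


def segment_signals(gt: np.ndarray, pred: np.ndarray) -> List[Segment]:
    """Split the timeline into maximal runs of constant ``(gt, pred)``."""
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError(f"signal length mismatch: {gt.shape} vs {pred.shape}")
    n = gt.size
    if n == 0:
        return []
    change = np.flatnonzero((gt[1:] != gt[:-1]) | (pred[1:] != pred[:-1])) + 1
    bounds = np.concatenate(([0], change, [n]))
    return [
        Segment(int(a), int(b), bool(gt[a]), bool(pred[a]))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def events_from_signal(signal: np.ndarray) -> List[Interval]:
    """Maximal positive runs of a boolean signal as half-open frame intervals."""
    signal = np.asarray(signal, dtype=bool)
    idx = np.flatnonzero(signal)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def _check_stream(events: Sequence[Interval], name: str) -> List[Interval]:
    evs = sorted((int(a), int(b)) for a, b in events)
    for a, b in evs:
        if b <= a:
            raise ValueError(f"{name}: empty or inverted interval ({a}, {b})")
    for (a1, b1), (a2, b2) in zip(evs, evs[1:]):
        if a2 < b1:
            raise ValueError(
                f"{name}: overlapping events ({a1},{b1}) and ({a2},{b2}); preprocess first"
            )
    return evs


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def score_events(
    gt_events: Sequence[Interval], pred_events: Sequence[Interval]
) -> EventErrorCounts:
    """Classify events of both streams into the Ward error classes.

    Inputs are half-open frame intervals of one AOI's ground-truth and
    prediction stream; "overlap" means at least one shared frame (events
    touching only at a boundary do not overlap).
    """
    gt = _check_stream(gt_events, "gt")
    pred = _check_stream(pred_events, "pred")
    gt_ov: List[List[int]] = [[] for _ in gt]
    pr_ov: List[List[int]] = [[] for _ in pred]
    for i, e in enumerate(gt):
        for j, r in enumerate(pred):
            if _overlaps(e, r):
                gt_ov[i].append(j)
                pr_ov[j].append(i)

    counts = EventErrorCounts()
    for i, e in enumerate(gt):
        js = gt_ov[i]
        if not js:
            counts.D += 1
            continue
        fragmented = len(js) >= 2
        merged = any(len(pr_ov[j]) >= 2 for j in js)
        if fragmented and merged:
            counts.FM += 1
        elif fragmented:
            counts.F += 1
        elif merged:
            counts.M += 1
        else:
            counts.C += 1
    for j, r in enumerate(pred):
        is_ = pr_ov[j]
        if not is_:
            counts.I_prime += 1
            continue
        merging = len(is_) >= 2
        fragmenting = any(len(gt_ov[i]) >= 2 for i in is_)
        if merging and fragmenting:
            counts.FM_prime += 1
        elif merging:
            counts.M_prime += 1
        elif fragmenting:
            counts.F_prime += 1
        # an exclusive 1:1 match is the same C already counted on the gt side
    return counts


def score_frames(
    segments: Sequence[Segment],
    gt_events: Sequence[Interval],
    pred_events: Sequence[Interval],
) -> FrameErrorCounts:
    """Project error classes to frames per segment.

    False-positive segments become merge frames when they lie between two
    ground-truth events spanned by one merging prediction, overfill frames
    when adjacent to a true-positive segment of the same prediction
    (``alpha`` before its first TP, ``omega`` after its last), and
    insertion frames otherwise.  False-negative segments symmetrically
    become fragmentation, underfill or deletion frames.  Each ``segment``'s
    ``frame_class`` attribute is annotated as a side effect.
    """
    gt = _check_stream(gt_events, "gt")
    pred = _check_stream(pred_events, "pred")
    counts = FrameErrorCounts()

    def containing(events: List[Interval], seg: Segment) -> Optional[Interval]:
        for a, b in events:
            if a <= seg.start_frame and seg.end_frame <= b:
                return (a, b)
        return None

    def any_overlap(events: List[Interval], lo: int, hi: int) -> bool:
        return lo < hi and any(_overlaps(ev, (lo, hi)) for ev in events)

    for seg in segments:
        n = seg.n_frames
        rating = seg.rating
        if rating == "TP":
            seg.frame_class = "TP"
            counts.TP += n
        elif rating == "TN":
            seg.frame_class = "TN"
            counts.TN += n
        elif rating == "FP":
            r = containing(pred, seg)
            if r is None:  # cannot happen for segments derived from the same signals
                raise ValueError("FP segment outside any prediction event")
            before = any_overlap(gt, r[0], seg.start_frame)
            after = any_overlap(gt, seg.end_frame, r[1])
            if before and after:
                seg.frame_class = "Mf"
                counts.Mf += n
            elif after:
                seg.frame_class = "Of_alpha"
                counts.Of_alpha += n
            elif before:
                seg.frame_class = "Of_omega"
                counts.Of_omega += n
            else:
                seg.frame_class = "If"
                counts.If += n
        else:  # FN
            e = containing(gt, seg)
            if e is None:
                raise ValueError("FN segment outside any ground-truth event")
            before = any_overlap(pred, e[0], seg.start_frame)
            after = any_overlap(pred, seg.end_frame, e[1])
            if before and after:
                seg.frame_class = "Ff"
                counts.Ff += n
            elif after:
                seg.frame_class = "Uf_alpha"
                counts.Uf_alpha += n
            elif before:
                seg.frame_class = "Uf_omega"
                counts.Uf_omega += n
            else:
                seg.frame_class = "Df"
                counts.Df += n
    return counts


def compute_metrics(ev: EventErrorCounts, fr: FrameErrorCounts) -> MetricRecord:
    """Derive the full metric record (percent scale) from raw counts."""
    rec = MetricRecord()
    rec.Pr = conservative_precision(ev.C, ev.R_total)
    rec.Re = conservative_recall(ev.C, ev.E_total)
    rec.Pr_star = progressive_precision(ev.I_prime, ev.R_total)
    rec.Re_star = progressive_recall(ev.D, ev.E_total)
    rec.f1 = f1_score(rec.Pr_star, rec.Re_star)
    P, N = fr.P, fr.N
    if P > 0:
        rec.dr = 100.0 * fr.Df / P
        rec.fr = 100.0 * fr.Ff / P
        rec.u_alpha = 100.0 * fr.Uf_alpha / P
        rec.u_omega = 100.0 * fr.Uf_omega / P
        rec.tpr = 100.0 * fr.TP / P
    if N > 0:
        rec.ir = 100.0 * fr.If / N
        rec.mr = 100.0 * fr.Mf / N
        rec.o_alpha = 100.0 * fr.Of_alpha / N
        rec.o_omega = 100.0 * fr.Of_omega / N
        rec.fpr = rec.ir + rec.mr + rec.o_alpha + rec.o_omega
    return rec


def aggregate(
    counts: Iterable[Tuple[EventErrorCounts, FrameErrorCounts]]
) -> Tuple[EventErrorCounts, FrameErrorCounts]:
    """Field-wise sums over recordings/AOIs (equivalent to concatenation).

    Ratios must be recomputed afterwards from the summed counts.
    """
    ev_total = EventErrorCounts()
    fr_total = FrameErrorCounts()
    for ev, fr in counts:
        ev_total = ev_total + ev
        fr_total = fr_total + fr
    return ev_total, fr_total


def is_failing(fr: FrameErrorCounts) -> Optional[bool]:
    """An AOI is failing when its deletion rate reaches 90%.

    Returns ``None`` when undefined (no positive ground-truth frames).
    """
    if fr.P == 0:
        return None
    return 100.0 * fr.Df / fr.P >= 90.0


def render_ead(ev: EventErrorCounts):
    """Event-analysis-diagram table: counts and ratios w.r.t. |E| and |R|.

    Ground-truth classes (D, F, FM, M) are shown against ``|E|``,
    prediction classes (FM', M', F', I') against ``|R|`` and correct events
    C against both.  Returns a pandas DataFrame.
    """
    import pandas as pd

    E, R = ev.E_total, ev.R_total
    rows = []
    for name, count, denom in [
        ("D", ev.D, E),
        ("F", ev.F, E),
        ("FM", ev.FM, E),
        ("M", ev.M, E),
        ("C", ev.C, None),
        ("FM'", ev.FM_prime, R),
        ("M'", ev.M_prime, R),
        ("F'", ev.F_prime, R),
        ("I'", ev.I_prime, R),
    ]:
        if name == "C":
            pct_e = 100.0 * count / E if E else None
            pct_r = 100.0 * count / R if R else None
        else:
            pct_e = 100.0 * count / denom if denom and name in ("D", "F", "FM", "M") else None
            pct_r = 100.0 * count / denom if denom and name not in ("D", "F", "FM", "M") else None
        rows.append({"class": name, "count": count, "pct_of_E": pct_e, "pct_of_R": pct_r})
    return pd.DataFrame(rows)


def plot_ead(ev: EventErrorCounts, path: str) -> None:
    """Stacked-bar EAD figure written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    E, R = ev.E_total, ev.R_total
    fig, ax = plt.subplots(figsize=(6, 2.5))
    gt_parts = [("D", ev.D), ("F", ev.F), ("FM", ev.FM), ("M", ev.M), ("C", ev.C)]
    pr_parts = [("C", ev.C), ("F'", ev.F_prime), ("FM'", ev.FM_prime), ("M'", ev.M_prime), ("I'", ev.I_prime)]
    for row, (parts, total) in enumerate([(gt_parts, E), (pr_parts, R)]):
        left = 0.0
        for name, count in parts:
            frac = 100.0 * count / total if total else 0.0
            ax.barh(row, frac, left=left, edgecolor="black")
            if frac > 4:
                ax.text(left + frac / 2, row, name, ha="center", va="center", fontsize=8)
            left += frac
    ax.set_yticks([0, 1])
    ax.set_yticklabels([f"|E|={E}", f"|R|={R}"])
    ax.set_xlabel("% of events")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# high-level drivers


def evaluate_signals(
    gt_signal: np.ndarray, pred_signal: np.ndarray
) -> Tuple[EventErrorCounts, FrameErrorCounts, MetricRecord]:
    """Score one AOI's boolean frame signals end to end."""
    gt_events = events_from_signal(gt_signal)
    pred_events = events_from_signal(pred_signal)
    segments = segment_signals(gt_signal, pred_signal)
    ev = score_events(gt_events, pred_events)
    fr = score_frames(segments, gt_events, pred_events)
    return ev, fr, compute_metrics(ev, fr)


def evaluate_streams(
    gt_events: Sequence[AttentionEvent],
    pred_events: Sequence[AttentionEvent],
    timeline: VideoMeta,
    preprocess: bool = True,
) -> Tuple[EventErrorCounts, FrameErrorCounts, MetricRecord]:
    """Score one AOI's ground-truth vs predicted attention events (in ms)."""
    ft = timeline.frame_duration
    if preprocess:
        gt_events = preprocess_events(gt_events, ft)
        pred_events = preprocess_events(pred_events, ft)
    return evaluate_signals(binarize(gt_events, timeline), binarize(pred_events, timeline))
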