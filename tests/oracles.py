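"""Independent brute-force oracles used to derive expected test values.

These deliberately avoid the package's implementation paths: event scoring
works directly off interval lists, frame scoring classifies frame by frame
(not per segment), and the attention-machine simulator is a standalone
transcription of the update rules.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

Interval = Tuple[int, int]


def enumerate_event_sets(n_frames: int, max_events: int) -> List[Tuple[Interval, ...]]:
    """All sets of up to ``max_events`` disjoint, non-adjacent half-open
    intervals on a timeline of ``n_frames`` frames."""
    results: List[Tuple[Interval, ...]] = []

    def rec(start: int, remaining: int, acc: List[Interval]) -> None:
        results.append(tuple(acc))
        if remaining == 0:
            return
        for a in range(start, n_frames):
            for b in range(a + 1, n_frames + 1):
                acc.append((a, b))
                rec(b + 1, remaining - 1, acc)  # +1 keeps events non-adjacent
                acc.pop()

    rec(0, max_events, [])
    return results


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def ward_event_oracle(gt: Sequence[Interval], pred: Sequence[Interval]) -> Dict[str, int]:
    """Brute-force event error classification from the class definitions."""
    counts = {k: 0 for k in ("D", "F", "FM", "M", "C", "I_prime", "F_prime", "FM_prime", "M_prime")}
    for e in gt:
        partners = [r for r in pred if _overlap(e, r)]
        if not partners:
            counts["D"] += 1
            continue
        fragmented = len(partners) >= 2
        merged = any(sum(_overlap(r, e2) for e2 in gt) >= 2 for r in partners)
        if fragmented and merged:
            counts["FM"] += 1
        elif fragmented:
            counts["F"] += 1
        elif merged:
            counts["M"] += 1
        else:
            counts["C"] += 1
    for r in pred:
        partners = [e for e in gt if _overlap(r, e)]
        if not partners:
            counts["I_prime"] += 1
            continue
        merging = len(partners) >= 2
        fragmenting = any(sum(_overlap(e, r2) for r2 in pred) >= 2 for e in partners)
        if merging and fragmenting:
            counts["FM_prime"] += 1
        elif merging:
            counts["M_prime"] += 1
        elif fragmenting:
            counts["F_prime"] += 1
    return counts


def ward_frame_oracle(gt_sig: Sequence[bool], pred_sig: Sequence[bool]) -> Dict[str, int]:
    """Frame-by-frame error classification (no segment machinery)."""
    n = len(gt_sig)
    counts = {k: 0 for k in ("Df", "Ff", "Uf_alpha", "Uf_omega", "TP", "If", "Mf",
                             "Of_alpha", "Of_omega", "TN")}

    def event_containing(sig: Sequence[bool], f: int) -> Interval:
        a = f
        while a > 0 and sig[a - 1]:
            a -= 1
        b = f + 1
        while b < n and sig[b]:
            b += 1
        return (a, b)

    for f in range(n):
        g, p = bool(gt_sig[f]), bool(pred_sig[f])
        if g and p:
            counts["TP"] += 1
        elif not g and not p:
            counts["TN"] += 1
        elif p:
            a, b = event_containing(pred_sig, f)
            before = any(gt_sig[a:f])
            after = any(gt_sig[f + 1:b])
            if before and after:
                counts["Mf"] += 1
            elif after:
                counts["Of_alpha"] += 1
            elif before:
                counts["Of_omega"] += 1
            else:
                counts["If"] += 1
        else:
            a, b = event_containing(gt_sig, f)
            before = any(pred_sig[a:f])
            after = any(pred_sig[f + 1:b])
            if before and after:
                counts["Ff"] += 1
            elif after:
                counts["Uf_alpha"] += 1
            elif before:
                counts["Uf_omega"] += 1
            else:
                counts["Df"] += 1
    return counts


def simulate_attention_machine(
    stream: Sequence[Tuple[str, float, float]],
    t_dur: float = 300.0,
    t_noise: float = 300.0,
    t_prob: float = 0.40,
) -> List[Tuple[str, str, float]]:
    """Standalone transcription of the duration/noise counter update rules.

    ``stream`` holds ``(label, probability, timestamp)`` tuples; the result
    holds ``(kind, label, corrected_timestamp)`` tuples.
    """
    cdur: Dict[str, float] = {}
    cnoise: Dict[str, float] = {}
    active = None
    last = None
    out: List[Tuple[str, str, float]] = []
    for label, p, t in stream:
        d = 0.0 if last is None else t - last
        last = t
        if p > t_prob:
            cdur[label] = cdur.get(label, 0.0) + d
            for k in cdur:
                if k != label and cdur[k] > 0:
                    cnoise[k] = cnoise.get(k, 0.0) + d
        else:
            for k in cdur:
                if cdur[k] > 0:
                    cnoise[k] = cnoise.get(k, 0.0) + d
        if cdur.get(label, 0.0) > t_dur:
            if active is not None and active != label:
                out.append(("ended", active, t - t_dur))
            out.append(("confirmed" if active == label else "started", label, t - t_dur))
            active = label
            cdur[label] = 0.0
            cnoise[label] = 0.0
        for k in list(cdur):
            if cnoise.get(k, 0.0) > t_noise:
                cdur[k] = 0.0
                cnoise[k] = 0.0
                if k == active:
                    out.append(("ended", k, t - t_dur))
                    active = None
    return out


def raster_point_in_polygon(x: float, y: float, verts: Sequence[Tuple[float, float]]) -> bool:
    """Shapely-backed containment oracle (boundary-inclusive) for simple polygons."""
    from shapely.geometry import Point, Polygon

    return Polygon(verts).intersects(Point(x, y))
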