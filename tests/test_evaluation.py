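import numpy as np
import pytest

from gazeaoi.core import AttentionEvent, VideoMeta
from gazeaoi.evaluation import (
    EventErrorCounts,
    FrameErrorCounts,
    aggregate,
    binarize,
    compute_metrics,
    conservative_recall,
    evaluate_signals,
    events_from_signal,
    is_failing,
    plot_ead,
    preprocess_events,
    progressive_recall,
    render_ead,
    score_events,
    score_frames,
    segment_signals,
)
from oracles import ward_event_oracle, ward_frame_oracle

META25 = VideoMeta(1920, 1080, 25.0, 100)


def ev(start, end, aoi="a"):
    return AttentionEvent(aoi=aoi, label=aoi, start=float(start), end=float(end))


def sig(bits):
    return np.array([c == "1" for c in bits], dtype=bool)


class TestPreprocess:
    def test_short_event_removed(self):
        assert preprocess_events([ev(0, 30)], 40.0) == []

    def test_adjacent_events_merged(self):
        out = preprocess_events([ev(0, 100), ev(120, 200)], 40.0)
        assert [(e.start, e.end) for e in out] == [(0.0, 200.0)]

    def test_gap_of_exactly_one_frame_not_merged(self):
        out = preprocess_events([ev(0, 100), ev(140, 200)], 40.0)
        assert len(out) == 2

    def test_different_aois_not_merged(self):
        out = preprocess_events([ev(0, 100, "a"), ev(120, 200, "b")], 40.0)
        assert len(out) == 2

    def test_empty(self):
        assert preprocess_events([], 40.0) == []


class TestBinarize:
    def test_midpoint_rule(self):
        signal = binarize([ev(0, 80)], META25)
        assert list(np.flatnonzero(signal)) == [0, 1]  # midpoints 20, 60

    def test_no_events_all_negative(self):
        assert not binarize([], META25).any()

    def test_full_span_all_positive(self):
        assert binarize([ev(0, META25.duration)], META25).all()


class TestSegmentSignals:
    def test_hand_example(self):
        segments = segment_signals(sig("000111"), sig("001110"))
        assert [(s.start_frame, s.end_frame, s.rating) for s in segments] == [
            (0, 2, "TN"),
            (2, 3, "FP"),
            (3, 5, "TP"),
            (5, 6, "FN"),
        ]

    def test_identical_constant_signals(self):
        assert len(segment_signals(sig("1111"), sig("1111"))) == 1

    def test_alternating(self):
        segments = segment_signals(sig("0101"), sig("0101"))
        assert [s.rating for s in segments] == ["TN", "TP", "TN", "TP"]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            segment_signals(sig("01"), sig("011"))


class TestScoreEvents:
    def test_identical_streams_all_correct(self):
        events = [(0, 5), (10, 15), (20, 25)]
        counts = score_events(events, events)
        assert counts.C == 3
        assert counts.E_total == counts.R_total == 3
        assert (counts.D, counts.F, counts.FM, counts.M) == (0, 0, 0, 0)
        assert (counts.I_prime, counts.F_prime, counts.FM_prime, counts.M_prime) == (0, 0, 0, 0)

    def test_merge(self):
        counts = score_events([(0, 10), (20, 30)], [(0, 30)])
        assert (counts.M, counts.M_prime, counts.C) == (2, 1, 0)

    def test_fragmentation(self):
        counts = score_events([(0, 30)], [(0, 10), (20, 30)])
        assert (counts.F, counts.F_prime, counts.C) == (1, 2, 0)

    def test_fragment_and_merge_compound(self):
        # one prediction fragments gt#0 (with another pred) and merges gt#1
        counts = score_events([(0, 10), (12, 20)], [(0, 3), (5, 15)])
        assert counts.FM == 1  # gt#0: fragmented and (via pred#1) merged
        assert counts.M == 1  # gt#1 overlapped by the merging pred only
        assert counts.FM_prime == 1  # pred#1 fragments gt#0 and merges both
        assert counts.F_prime == 1  # pred#0
        oracle = ward_event_oracle([(0, 10), (12, 20)], [(0, 3), (5, 15)])
        for key, value in oracle.items():
            assert getattr(counts, key) == value

    def test_boundary_touch_is_not_overlap(self):
        counts = score_events([(0, 10)], [(10, 20)])
        assert counts.D == 1
        assert counts.I_prime == 1

    def test_overlapping_stream_rejected(self):
        with pytest.raises(ValueError):
            score_events([(0, 10), (5, 15)], [])

    def test_c_equal_from_both_sides_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            gt = sorted(set(map(tuple, rng.integers(0, 30, (4, 2)))))
            gt = [(a, b) for a, b in gt if a < b]
            gt = _make_disjoint(gt)
            pred = _make_disjoint(
                [(a, b) for a, b in sorted(set(map(tuple, rng.integers(0, 30, (4, 2))))) if a < b]
            )
            counts = score_events(gt, pred)
            assert counts.E_total == len(gt)
            assert counts.R_total == len(pred)


def _make_disjoint(intervals):
    out = []
    last_end = -1
    for a, b in intervals:
        a = max(a, last_end + 1)
        if a < b:
            out.append((a, b))
            last_end = b
    return out


class TestScoreFrames:
    def run(self, gt_bits, pred_bits):
        gt_sig, pred_sig = sig(gt_bits), sig(pred_bits)
        segments = segment_signals(gt_sig, pred_sig)
        return score_frames(segments, events_from_signal(gt_sig), events_from_signal(pred_sig))

    def test_underfill_overfill_example(self):
        # gt [10,50), pred [20,60) on a unit frame grid
        n = 70
        gt_sig = np.zeros(n, bool)
        gt_sig[10:50] = True
        pred_sig = np.zeros(n, bool)
        pred_sig[20:60] = True
        segments = segment_signals(gt_sig, pred_sig)
        fr = score_frames(segments, events_from_signal(gt_sig), events_from_signal(pred_sig))
        assert fr.Uf_alpha == 10
        assert fr.TP == 30
        assert fr.Of_omega == 10
        assert fr.Df == fr.Ff == fr.Uf_omega == 0
        assert fr.If == fr.Mf == fr.Of_alpha == 0

    def test_pure_insertion(self):
        fr = self.run("000000", "011110")
        assert fr.If == 4
        assert fr.TN == 2

    def test_merge_frames(self):
        # gt [0,10),[20,30), pred [0,30): frames [10,20) are merge frames
        n = 30
        gt_sig = np.zeros(n, bool)
        gt_sig[0:10] = True
        gt_sig[20:30] = True
        pred_sig = np.ones(n, bool)
        segments = segment_signals(gt_sig, pred_sig)
        fr = score_frames(segments, events_from_signal(gt_sig), events_from_signal(pred_sig))
        assert fr.Mf == 10
        assert fr.TP == 20

    def test_fragmentation_frames(self):
        fr = self.run("11111111", "11000011")
        assert fr.Ff == 4
        assert fr.TP == 4

    def test_pure_deletion(self):
        fr = self.run("0111100", "0000000")
        assert fr.Df == 4

    def test_matches_frame_oracle_random(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            gt_sig = rng.random(24) < 0.4
            pred_sig = rng.random(24) < 0.4
            segments = segment_signals(gt_sig, pred_sig)
            fr = score_frames(segments, events_from_signal(gt_sig), events_from_signal(pred_sig))
            oracle = ward_frame_oracle(gt_sig.tolist(), pred_sig.tolist())
            for key, value in oracle.items():
                assert getattr(fr, key) == value, (key, gt_sig.astype(int), pred_sig.astype(int))


class TestComputeMetrics:
    def test_conservative_recall_printed_counts(self):
        # C=371 correct of |E|=2438 ground-truth events
        assert round(conservative_recall(371, 2438), 2) == 15.22

    def test_progressive_recall_complement(self):
        # D/|E| = 66.41% -> Re* = 33.59%
        assert round(100.0 - 66.41, 2) == 33.59
        ev_counts = EventErrorCounts(D=6641, F=0, FM=0, M=0, C=3359)
        rec = compute_metrics(ev_counts, FrameErrorCounts())
        assert rec.Re_star == pytest.approx(33.59)

    def test_f1_symmetric_fixed_point(self):
        ev_counts = EventErrorCounts(D=1, C=1, I_prime=1)
        rec = compute_metrics(ev_counts, FrameErrorCounts())
        assert rec.Pr_star == pytest.approx(50.0)
        assert rec.Re_star == pytest.approx(50.0)
        assert rec.f1 == pytest.approx(50.0)

    def test_undefined_ratios_absent(self):
        rec = compute_metrics(EventErrorCounts(), FrameErrorCounts())
        assert rec.Pr is None and rec.Re is None
        assert rec.Pr_star is None and rec.Re_star is None
        assert rec.dr is None and rec.ir is None

    def test_rate_decompositions(self):
        gt_sig = sig("0111101100011110000000")
        pred_sig = sig("0011111110010010011000")
        ev_counts, fr_counts, rec = evaluate_signals(gt_sig, pred_sig)
        assert rec.fpr == pytest.approx(rec.ir + rec.mr + rec.o_alpha + rec.o_omega)
        assert 100.0 - rec.tpr == pytest.approx(rec.dr + rec.fr + rec.u_alpha + rec.u_omega)


class TestAggregate:
    def test_two_participants(self):
        a = (EventErrorCounts(C=1, D=1), FrameErrorCounts(TP=5))
        b = (EventErrorCounts(C=3, D=1), FrameErrorCounts(TP=7))
        ev_counts, fr_counts = aggregate([a, b])
        assert ev_counts.C == 4
        assert ev_counts.E_total == 6
        rec = compute_metrics(ev_counts, fr_counts)
        assert rec.Re == pytest.approx(100.0 * 4 / 6)

    def test_identity_and_empty(self):
        ev_counts, fr_counts = aggregate([])
        assert ev_counts.E_total == 0 and fr_counts.P == 0
        single = (EventErrorCounts(C=2), FrameErrorCounts(TP=3))
        ev_counts, fr_counts = aggregate([single])
        assert ev_counts.C == 2 and fr_counts.TP == 3

    def test_aggregation_commutes_with_concatenation(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a_gt = rng.random(20) < 0.4
            a_pred = rng.random(20) < 0.4
            b_gt = rng.random(20) < 0.4
            b_pred = rng.random(20) < 0.4
            # recordings separated by one all-negative frame
            a_gt[-1] = a_pred[-1] = b_gt[-1] = b_pred[-1] = False
            gt_cat = np.concatenate([a_gt, b_gt])
            pred_cat = np.concatenate([a_pred, b_pred])
            ev_a, fr_a, _ = evaluate_signals(a_gt, a_pred)
            ev_b, fr_b, _ = evaluate_signals(b_gt, b_pred)
            ev_sum, fr_sum = aggregate([(ev_a, fr_a), (ev_b, fr_b)])
            ev_cat, fr_cat, _ = evaluate_signals(gt_cat, pred_cat)
            assert ev_sum == ev_cat
            assert fr_sum == fr_cat


class TestIsFailing:
    def test_boundary(self):
        assert is_failing(FrameErrorCounts(Df=100)) is True  # dr = 100%
        assert is_failing(FrameErrorCounts(Df=90, TP=10)) is True  # dr = 90%
        assert is_failing(FrameErrorCounts(Df=899, TP=101)) is False  # dr = 89.9%

    def test_undefined_when_no_positives(self):
        assert is_failing(FrameErrorCounts(TN=10)) is None


class TestRenderEAD:
    def test_all_correct(self):
        df = render_ead(EventErrorCounts(C=5))
        row = df[df["class"] == "C"].iloc[0]
        assert row["count"] == 5
        assert row["pct_of_E"] == pytest.approx(100.0)
        assert row["pct_of_R"] == pytest.approx(100.0)

    def test_fragmenting_counts_shown_against_r_and_e(self):
        # F' against |R|, F against |E|
        ev_counts = EventErrorCounts(D=1619, F=60, FM=13, M=375, C=371,
                                     I_prime=48, F_prime=206, FM_prime=10, M_prime=166)
        df = render_ead(ev_counts).set_index("class")
        R = ev_counts.R_total
        assert df.loc["F'", "pct_of_R"] == pytest.approx(100.0 * 206 / R)
        pct_e = df.loc["F'", "pct_of_E"]
        assert pct_e is None or np.isnan(pct_e)
        assert df.loc["F", "pct_of_E"] == pytest.approx(100.0 * 60 / ev_counts.E_total)

    def test_zero_counts(self):
        df = render_ead(EventErrorCounts())
        assert (df["count"] == 0).all()

    def test_plot_smoke(self, tmp_path):
        plot_ead(EventErrorCounts(C=3, D=1, I_prime=2), str(tmp_path / "ead.png"))
        assert (tmp_path / "ead.png").exists()
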