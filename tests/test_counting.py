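import numpy as np
import pytest

from pigtrack.boxes import Box
from pigtrack.correction import CountingStats
from pigtrack.counting import (TrackRecord, compute_stats, count_stream,
                               detect_turnback, update_records, valid_count)
from pigtrack.sim import (DetectionNoise, SimParams, TurnbackSpec,
                          edge_flicker_scenario, generate_scenario,
                          oracle_detections)
from pigtrack.tracker import TrackerConfig


def record_from(vs, gamma=2.0, h=60.0, start=0):
    rec = TrackRecord(1)
    for k, v in enumerate(vs):
        rec.append(start + k, Box(v, 100.0, gamma, h))
    return rec


class TestRecords:
    def test_n_counts_frames(self):
        records = {}
        for f in range(7):
            update_records(records, [(3, Box(10 + f, 10, 2, 5))], f)
        assert records[3].n == 7
        assert records[3].v_series == [10 + f for f in range(7)]

    def test_duplicate_id_in_frame_rejected(self):
        with pytest.raises(ValueError):
            update_records({}, [(1, Box(10, 10, 2, 5)), (1, Box(20, 10, 2, 5))], 0)

    def test_empty_frame_is_noop(self):
        records = {}
        update_records(records, [], 0)
        assert records == {}


class TestComputeStats:
    def test_mean_length_and_max_area(self):
        t30 = [Box(0, 0, 2.0, 100.0)] * 30   # area 20000
        t50 = [Box(0, 0, 3.0, 200.0)] * 50   # area 120000
        stats = compute_stats([t30, t50])
        assert stats.z == pytest.approx(40.0)
        assert stats.s == pytest.approx(120_000.0)

    def test_equal_lengths(self):
        stats = compute_stats([[Box(0, 0, 2, 50)] * 25] * 3)
        assert stats.z == 25.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_stats([])


class TestValidCount:
    stats = CountingStats(s=120_000.0, z=40.0)

    def test_persistent_complete_pig_counted(self):
        rec = record_from(np.linspace(100, 800, 30), gamma=1.944, h=190)  # max area ~70000
        d = valid_count(rec, self.stats)
        assert d.counted and d.area_margin > 0 and d.frame_margin > 0

    def test_edge_flicker_too_few_frames(self):
        rec = record_from([5, 6, 7], gamma=3.0, h=200)  # n=3 < z/2
        assert not valid_count(rec, self.stats).counted

    def test_never_fully_visible_not_counted(self):
        rec = record_from(np.linspace(100, 800, 30), gamma=2.0, h=100)  # 20000 < 60000
        assert not valid_count(rec, self.stats).counted

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            valid_count(TrackRecord(1), self.stats)


class TestTurnback:
    W = 672.0

    def test_monotone_crossing_no_event(self):
        rec = record_from(np.linspace(10, 660, 60))
        assert detect_turnback(rec, self.W) == []

    def test_enter_cross_mid_return_decrements(self):
        v = np.concatenate([np.linspace(10, 400, 40), np.linspace(400, 10, 40)])
        events = detect_turnback(record_from(v), self.W)
        assert len(events) == 1
        assert events[0].entry_side == events[0].exit_side == "left"

    def test_jitter_below_hysteresis_ignored(self):
        rng = np.random.default_rng(0)
        v = np.linspace(10, 660, 80) + rng.normal(0, 5, 80)  # wiggle << 67 px hysteresis
        assert detect_turnback(record_from(v), self.W) == []

    def test_cross_return_cross_exits_far_side_no_decrement(self):
        v = np.concatenate([np.linspace(10, 600, 40), np.linspace(600, 200, 25),
                            np.linspace(200, 660, 35)])
        assert detect_turnback(record_from(v), self.W) == []


class TestCountStream:
    def test_empty_stream_counts_zero(self):
        res = count_stream([], TrackerConfig(), CountingStats(), frame_width=672)
        assert res.count == 0

    def test_five_clean_crossings_count_five(self):
        gt = generate_scenario(SimParams(n_pigs=5, scale=0.25), 41)
        dets = oracle_detections(gt, DetectionNoise(), 41)
        stats = compute_stats(gt.tracks())
        res = count_stream(dets, TrackerConfig(), stats, frame_width=gt.frame_width)
        assert res.count == 5

    def test_turnback_pig_not_counted_net(self):
        gt = generate_scenario(
            SimParams(n_pigs=3, scale=0.25, turnbacks=(TurnbackSpec(1, 0.6),)), 7)
        dets = oracle_detections(gt, DetectionNoise(), 7)
        stats = compute_stats(gt.tracks())
        res = count_stream(dets, TrackerConfig(), stats, frame_width=gt.frame_width)
        assert res.count == 2
        assert res.state.turnback_adjustments == 1

    def test_edge_flicker_counted_once(self):
        gt = edge_flicker_scenario(5)
        dets = oracle_detections(gt, seed=5)
        stats = CountingStats().scaled(0.25)
        res = count_stream(dets, TrackerConfig(), stats, frame_width=gt.frame_width)
        assert res.count == 1
        assert len(res.distinct_ids) > 1  # naive id counting would overcount

    def test_count_never_negative_and_audit_consistent(self):
        gt = generate_scenario(
            SimParams(n_pigs=2, scale=0.25, turnbacks=(TurnbackSpec(0, 0.55),
                                                       TurnbackSpec(1, 0.6))), 9)
        dets = oracle_detections(gt, DetectionNoise(), 9)
        stats = compute_stats(gt.tracks())
        res = count_stream(dets, TrackerConfig(), stats, frame_width=gt.frame_width)
        assert res.count >= 0
        counted_events = [e for e in res.audit if e.event == "counted"]
        assert len(counted_events) == len(res.state.counted)

    def test_breeding_mode_counts_resident_pigs(self):
        gt = generate_scenario(SimParams(n_pigs=4, scale=0.25, mode="breeding",
                                         duration=250), 13)
        dets = oracle_detections(gt, DetectionNoise(), 13)
        stats = compute_stats(gt.tracks())
        res = count_stream(dets, TrackerConfig(mode="breeding"), stats,
                          frame_width=gt.frame_width)
        assert res.count == 4
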