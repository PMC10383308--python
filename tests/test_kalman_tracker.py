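import numpy as np
import pytest

from pigtrack.boxes import Box
from pigtrack.kalman import KalmanFilter
from pigtrack.sim import DetectionNoise, SimParams, generate_scenario, oracle_detections
from pigtrack.tracker import (Detection, Tracker, TrackerConfig, TrackStatus,
                              associate, nms)


class TestKalman:
    def setup_method(self):
        self.kf = KalmanFilter()

    def test_zero_velocity_keeps_position(self):
        mean, cov = self.kf.initiate(np.array([100.0, 50.0, 2.0, 40.0]))
        m2, _ = self.kf.predict(mean, cov)
        assert np.allclose(m2[:4], mean[:4])

    def test_velocity_advances_position(self):
        mean, cov = self.kf.initiate(np.array([100.0, 50.0, 2.0, 40.0]))
        mean[4] = 5.0
        m2, _ = self.kf.predict(mean, cov)
        assert m2[0] == pytest.approx(105.0)

    def test_predict_grows_uncertainty(self):
        mean, cov = self.kf.initiate(np.array([100.0, 50.0, 2.0, 40.0]))
        _, c2 = self.kf.predict(mean, cov)
        assert np.trace(c2) > np.trace(cov)

    def test_update_with_prediction_is_noop(self):
        mean, cov = self.kf.initiate(np.array([100.0, 50.0, 2.0, 40.0]))
        mean, cov = self.kf.predict(mean, cov)
        m2, _ = self.kf.update(mean, cov, mean[:4].copy())
        assert np.allclose(m2[:4], mean[:4], atol=1e-9)

    def test_tiny_measurement_noise_snaps_to_measurement(self):
        mean, cov = self.kf.initiate(np.array([100.0, 50.0, 2.0, 40.0]))
        mean, cov = self.kf.predict(mean, cov)
        z = np.array([130.0, 60.0, 2.2, 44.0])
        m2, _ = self.kf.update(mean, cov, z, meas_scale=1e-6)
        assert np.allclose(m2[:4], z, atol=1e-3)

    def test_repeated_updates_converge_to_fixed_measurement(self):
        mean, cov = self.kf.initiate(np.array([0.0, 0.0, 2.0, 40.0]))
        z = np.array([60.0, 30.0, 2.0, 40.0])
        for _ in range(60):
            mean, cov = self.kf.predict(mean, cov)
            mean, cov = self.kf.update(mean, cov, z)
        assert np.allclose(mean[:4], z, atol=0.5)

    def test_covariance_stays_symmetric_psd(self):
        rng = np.random.default_rng(0)
        mean, cov = self.kf.initiate(np.array([100.0, 50.0, 2.0, 40.0]))
        for _ in range(30):
            mean, cov = self.kf.predict(mean, cov)
            z = mean[:4] + rng.normal(0, 2, 4)
            mean, cov = self.kf.update(mean, cov, z)
            assert np.allclose(cov, cov.T, atol=1e-8)
            assert np.linalg.eigvalsh(cov).min() > -1e-8


def det(cx, cy, g, h, conf=1.0, feature=None):
    return Detection(Box(cx, cy, g, h), conf, feature)


class TestAssociate:
    def test_coincident_detection_matches(self):
        tr = Tracker(TrackerConfig(n_init=1))
        tr.step([det(100, 100, 2, 40)], 0)
        matches, ut, ud = associate(tr.tracks, [det(100, 100, 2, 40)], tr.config)
        assert matches == [(0, 0)] and not ut and not ud

    def test_far_and_dissimilar_detection_unmatched(self):
        feat_a = np.zeros(8, dtype=np.float32)
        feat_a[0] = 1.0
        feat_b = np.zeros(8, dtype=np.float32)
        feat_b[1] = 1.0  # cosine distance 1.0 > gate 0.1
        tr = Tracker(TrackerConfig(n_init=1))
        tr.step([det(100, 100, 2, 40, feature=feat_a)], 0)
        matches, ut, ud = associate(tr.tracks, [det(600, 400, 2, 40, feature=feat_b)],
                                    tr.config)
        assert not matches and ut == [0] and ud == [0]

    def test_features_decide_among_gated_candidates(self):
        # two crossed detections, both within each track's motion gate:
        # appearance must decide, matching the brute-force best assignment
        fa = np.zeros(8, dtype=np.float32); fa[0] = 1.0
        fb = np.zeros(8, dtype=np.float32); fb[1] = 1.0
        tr = Tracker(TrackerConfig(n_init=1))
        tr.step([det(100, 100, 1, 100, feature=fa), det(132, 100, 1, 100, feature=fb)], 0)
        dets = [det(130, 100, 1, 100, feature=fa), det(102, 100, 1, 100, feature=fb)]
        matches, _, _ = associate(tr.tracks, dets, tr.config)
        got = {(tr.tracks[t].id, d) for t, d in matches}
        # brute force over both pairings: feature-consistent one is cheaper
        assert got == {(1, 0), (2, 1)}

    def test_empty_inputs(self):
        assert associate([], [], TrackerConfig()) == ([], [], [])


class TestLifecycle:
    def test_no_detections_no_tracks(self):
        tr = Tracker(TrackerConfig())
        for f in range(10):
            assert tr.step([], f) == []
        assert tr.tracks == []

    def test_single_pig_single_id(self):
        tr = Tracker(TrackerConfig())
        ids = set()
        for f in range(10):
            out = tr.step([det(100 + 5 * f, 100, 2, 40)], f)
            ids |= {t.id for t in out}
        assert len(ids) == 1

    def test_confirmation_needs_n_init_hits(self):
        tr = Tracker(TrackerConfig(n_init=3))
        assert tr.step([det(100, 100, 2, 40)], 0) == []
        assert tr.step([det(100, 100, 2, 40)], 1) == []
        assert len(tr.step([det(100, 100, 2, 40)], 2)) == 1

    def test_aisle_deletes_after_max_age_breeding_retains(self):
        for mode, expect_same in [("aisle", False), ("breeding", True)]:
            tr = Tracker(TrackerConfig(n_init=1, max_age=5, mode=mode))
            first = tr.step([det(100, 100, 2, 40)], 0)[0].id
            f = 1
            for _ in range(10):  # gap longer than max_age
                tr.step([], f)
                f += 1
            out = tr.step([det(100, 100, 2, 40)], f)
            # aisle: old track deleted, new id; breeding: same id survives
            assert (out and out[0].id == first) == expect_same

    def test_ids_strictly_increasing_never_reused(self):
        tr = Tracker(TrackerConfig(n_init=1, max_age=2))
        seen = []
        for f in range(0, 40, 4):
            out = tr.step([det(100, 100, 2, 40)], f)
            tr.step([], f + 1), tr.step([], f + 2), tr.step([], f + 3)
            seen.extend(t.id for t in out)
        assert seen == sorted(set(seen))

    def test_out_of_order_frames_rejected(self):
        tr = Tracker(TrackerConfig())
        tr.step([], 5)
        with pytest.raises(ValueError):
            tr.step([], 5)

    def test_low_confidence_filtered(self):
        tr = Tracker(TrackerConfig(n_init=1))
        out = tr.step([det(100, 100, 2, 40, conf=0.4)], 0)
        assert out == [] and tr.tracks == []

    def test_nms_suppresses_overlaps(self):
        kept = nms([det(100, 100, 2, 40, 0.9), det(102, 100, 2, 40, 0.8),
                    det(300, 100, 2, 40, 0.7)], max_overlap=0.6)
        assert len(kept) == 2


class TestOnScenarios:
    def test_clean_pigs_one_id_each_no_switches(self):
        params = SimParams(n_pigs=4, scale=0.25)
        gt = generate_scenario(params, 17)
        dets = oracle_detections(gt, DetectionNoise(), 17)
        tr = Tracker(TrackerConfig())
        ids = set()
        for f, dd in enumerate(dets):
            ids |= {t.id for t in tr.step(dd, f)}
        assert len(ids) == 4

    def test_appearance_gate_never_hurts_crossing_pigs(self):
        # disabling the appearance gate cannot reduce id switches
        def distinct_ids(max_dist):
            params = SimParams(n_pigs=6, scale=0.25, crowding_pairs=1)
            gt = generate_scenario(params, 23)
            dets = oracle_detections(gt, DetectionNoise(with_features=True,
                                                        jitter_sigma=2.0), 23)
            tr = Tracker(TrackerConfig(max_dist=max_dist))
            ids = set()
            for f, dd in enumerate(dets):
                ids |= {t.id for t in tr.step(dd, f)}
            return len(ids)

        assert distinct_ids(0.1) <= distinct_ids(1e9)
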