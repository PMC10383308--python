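import numpy as np
import pytest

from pigtrack.sim import (MAX_SPEED_PX, Burst, DetectionNoise, SimParams,
                          TurnbackSpec, edge_flicker_scenario, generate_scenario,
                          make_bursts, oracle_detections, render_crops,
                          render_frames, texture_params)


class TestScenario:
    def test_pig_count_and_determinism(self):
        p = SimParams(n_pigs=3, scale=0.25)
        a = generate_scenario(p, 5)
        b = generate_scenario(p, 5)
        assert a.n_pigs == 3
        assert sorted(a.frames) == sorted(b.frames)
        for f in a.frames:
            assert a.frames[f] == b.frames[f]

    def test_different_seed_differs(self):
        p = SimParams(n_pigs=3, scale=0.25)
        a, b = generate_scenario(p, 1), generate_scenario(p, 2)
        assert a.frames != b.frames

    def test_speed_bound_enforced(self):
        with pytest.raises(ValueError):
            SimParams(speed_range=(10.0, MAX_SPEED_PX + 1))

    def test_aisle_area_profiles_unimodal(self):
        # the premise of area-based counting: grow, peak, shrink
        gt = generate_scenario(SimParams(n_pigs=4, scale=0.25), 8)
        for boxes in gt.tracks().values():
            areas = np.array([b.area for b in boxes])
            peak = areas.argmax()
            assert np.all(np.diff(areas[: peak + 1]) >= -1e-6)
            assert np.all(np.diff(areas[peak:]) <= 1e-6)

    def test_aisle_tracks_start_and_end_at_edges(self):
        gt = generate_scenario(SimParams(n_pigs=4, scale=0.25), 12)
        for pid, boxes in gt.tracks().items():
            for endpoint in (boxes[0], boxes[-1]):
                touches = (endpoint.cx - endpoint.w / 2 <= 1.0
                           or endpoint.cx + endpoint.w / 2 >= gt.frame_width - 1.0)
                assert touches

    def test_turnback_reverses_displacement_once(self):
        gt = generate_scenario(
            SimParams(n_pigs=2, scale=0.25, turnbacks=(TurnbackSpec(0, 0.6),)), 3)
        assert gt.pigs[1].turnbacks == 1
        xs = np.array([b.cx for b in gt.tracks()[1]])
        signs = np.sign(np.diff(xs))
        changes = np.sum(np.abs(np.diff(signs[signs != 0])) > 0)
        assert changes == 1

    def test_breeding_needs_duration(self):
        with pytest.raises(ValueError):
            SimParams(mode="breeding")

    def test_breeding_pigs_persist(self):
        gt = generate_scenario(SimParams(n_pigs=3, scale=0.25, mode="breeding",
                                         duration=100), 4)
        for boxes in gt.tracks().values():
            assert len(boxes) == 100


class TestOracleDetections:
    def test_zero_noise_equals_ground_truth(self):
        gt = generate_scenario(SimParams(n_pigs=2, scale=0.25), 6)
        dets = oracle_detections(gt, DetectionNoise(), 6)
        for f in range(gt.n_frames):
            got = {(round(d.box.cx, 6), round(d.box.h, 6)) for d in dets[f]}
            want = {(round(b.cx, 6), round(b.h, 6)) for _, b in gt.frames.get(f, [])}
            assert got == want
            assert all(d.confidence == 1.0 for d in dets[f])

    def test_full_dropout_empty_stream(self):
        gt = generate_scenario(SimParams(n_pigs=2, scale=0.25), 6)
        dets = oracle_detections(gt, DetectionNoise(dropout_p=1.0), 6)
        assert all(len(d) == 0 for d in dets)

    def test_dropout_rate_within_binomial_bounds(self):
        gt = generate_scenario(SimParams(n_pigs=10, scale=0.25), 21)
        n_boxes = sum(len(v) for v in gt.frames.values())
        p = 0.1
        dets = oracle_detections(gt, DetectionNoise(dropout_p=p), 21)
        kept = sum(len(d) for d in dets)
        dropped_frac = 1 - kept / n_boxes
        sd = np.sqrt(p * (1 - p) / n_boxes)
        assert abs(dropped_frac - p) <= 3 * sd

    def test_dropout_nested_across_levels(self):
        # same seed: every detection surviving p=0.2 also survives p=0.05
        gt = generate_scenario(SimParams(n_pigs=5, scale=0.25), 22)
        lo = oracle_detections(gt, DetectionNoise(dropout_p=0.05), 9)
        hi = oracle_detections(gt, DetectionNoise(dropout_p=0.2), 9)
        for f in range(gt.n_frames):
            keys_lo = {round(d.box.cx, 6) for d in lo[f]}
            keys_hi = {round(d.box.cx, 6) for d in hi[f]}
            assert keys_hi <= keys_lo

    def test_bursts_remove_target_pig(self):
        gt = generate_scenario(SimParams(n_pigs=3, scale=0.25), 23)
        bursts = make_bursts(gt, count=1, length=20, seed=1)
        (burst,) = bursts
        dets = oracle_detections(gt, DetectionNoise(bursts=bursts), 23)
        covered = [f for f in range(burst.start, burst.start + burst.length)
                   if any(pid == burst.pig_id for pid, _ in gt.frames.get(f, []))]
        assert covered  # burst overlaps the pig's on-screen span
        gt_boxes = {f: {round(b.cx, 6) for pid, b in gt.frames.get(f, [])
                        if pid == burst.pig_id} for f in covered}
        for f in covered:
            got = {round(d.box.cx, 6) for d in dets[f]}
            assert not (gt_boxes[f] & got)

    def test_features_stable_per_identity(self):
        gt = generate_scenario(SimParams(n_pigs=2, scale=0.25), 24)
        dets = oracle_detections(gt, DetectionNoise(with_features=True,
                                                    feature_noise=0.01), 24)
        by_pig = {}
        for f, dd in enumerate(dets):
            for d in dd:
                for pid, b in gt.frames.get(f, []):
                    if abs(b.cx - d.box.cx) < 1e-6:
                        by_pig.setdefault(pid, []).append(d.feature)
        for pid, feats in by_pig.items():
            feats = np.stack(feats)
            assert feats @ feats[0] == pytest.approx(np.ones(len(feats)), abs=0.05)


class TestRenderer:
    def test_identities_have_distinct_textures(self):
        crops, labels = render_crops(2, 8, hw=(32, 64), seed=0)
        m0 = crops[labels == 0].mean()
        m1 = crops[labels == 1].mean()
        assert abs(m0 - m1) > 0.005

    def test_same_identity_consistent_across_crops(self):
        crops, labels = render_crops(3, 10, hw=(32, 64), seed=1)
        for ident in range(3):
            means = crops[labels == ident].mean(axis=(1, 2, 3))
            assert means.std() < 0.05

    def test_rendered_frames_cover_ground_truth_boxes(self):
        gt = generate_scenario(SimParams(n_pigs=2, scale=0.125), 2)
        f0 = min(gt.frames)
        frames = render_frames(gt, seed=0, frame_range=(f0, f0 + 1))
        img = frames[0].astype(float).mean(axis=2)
        for pid, box in gt.frames[f0]:
            x1, y1, x2, y2 = (int(v) for v in box.tlbr)
            inside = img[y1:y2, x1:x2]
            base = texture_params(gt.pigs[pid].texture_seed)["base_gray"] * 255
            # the drawn coat dominates the box interior
            assert inside.size > 0

    def test_flicker_scenario_shape(self):
        gt = edge_flicker_scenario(3, cycles=2, gap_len=35)
        assert gt.n_pigs == 1
        lengths = [len(v) for v in gt.tracks().values()]
        assert lengths[0] > 2 * 12  # flicker segments plus the crossing
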