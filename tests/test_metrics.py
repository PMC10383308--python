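import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pigtrack.boxes import Box
from pigtrack.metrics import accuracy, clearmot, counting_eval, detection_pr, mean_ap


def b(x, y, w=10.0, h=10.0):
    return Box.from_tlwh(x, y, w, h)


class TestDetectionPR:
    def test_perfect_predictions(self):
        gt = {0: [b(0, 0), b(50, 0)], 1: [b(0, 0)]}
        preds = {f: [(box, 0.9) for box in boxes] for f, boxes in gt.items()}
        out = detection_pr(preds, gt)
        assert out.precision == 1.0 and out.recall == 1.0 and out.ap == 1.0

    def test_no_predictions(self):
        out = detection_pr({}, {0: [b(0, 0)]})
        assert out.recall == 0.0 and out.ap == 0.0

    def test_hand_stepped_pr_curve(self):
        # 3 truths; 2 correct predictions then a lower-confidence false
        # positive: PR steps (1, 1/3), (1, 2/3), (2/3, 2/3) -> AP = 2/3
        gt = {0: [b(0, 0), b(50, 0), b(100, 0)]}
        preds = {0: [(b(0, 0), 0.9), (b(50, 0), 0.8), (b(200, 0), 0.7)]}
        out = detection_pr(preds, gt)
        assert out.ap == pytest.approx(2.0 / 3.0)
        assert out.tp == 2 and out.fp == 1 and out.fn == 1

    def test_matches_bruteforce_integration_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n_gt, n_pred = rng.integers(1, 8), rng.integers(1, 8)
            gt = {0: [b(20 * i, 0) for i in range(n_gt)]}
            preds = {0: [(b(20 * rng.integers(0, 10) + rng.normal(0, 2), 0),
                          float(rng.random())) for _ in range(n_pred)]}
            out = detection_pr(preds, gt)
            # oracle: sort by confidence, accumulate, integrate envelope
            from pigtrack.boxes import iou
            flags = []
            used = set()
            for box, conf in sorted(preds[0], key=lambda t: -t[1]):
                hit = None
                best = 0.5
                for j, g in enumerate(gt[0]):
                    if j in used:
                        continue
                    o = iou(box, g)
                    if o >= best:
                        best, hit = o, j
                if hit is not None:
                    used.add(hit)
                    flags.append(True)
                else:
                    flags.append(False)
            tp = np.cumsum(flags)
            fp = np.cumsum([not f for f in flags])
            rec = tp / n_gt
            prec = tp / (tp + fp)
            ap = 0.0
            prev_r = 0.0
            for i in range(len(rec)):
                p_max = max(prec[i:])
                ap += (rec[i] - prev_r) * p_max
                prev_r = rec[i]
            assert out.ap == pytest.approx(ap, abs=1e-9)

    def test_mean_ap_over_thresholds_bounded_by_ap50(self):
        gt = {0: [b(0, 0), b(50, 0)]}
        preds = {0: [(b(1, 1), 0.9), (b(51, 2), 0.8)]}
        assert mean_ap(preds, gt) <= detection_pr(preds, gt, 0.5).ap + 1e-12


class TestAccuracy:
    @pytest.mark.parametrize("counts,expected", [
        ((9, 0, 1, 0), 0.9), ((5, 5, 0, 0), 1.0), ((2, 2, 2, 2), 0.5)])
    def test_cases(self, counts, expected):
        assert accuracy(*counts) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            accuracy(0, 0, 0, 0)


class TestClearMot:
    def make_tracks(self, n_frames, ids_boxes):
        return {f: [(i, bx) for i, bx in ids_boxes] for f in range(n_frames)}

    def test_identical_tracks_perfect(self):
        gt = self.make_tracks(10, [(1, b(0, 0)), (2, b(50, 0))])
        out = clearmot(gt, gt)
        assert out.mota == 1.0 and out.motp == 0.0

    def test_eq_substitution_case(self):
        # sum g = 20, misses 2, fp 1, mismatches 1 -> MOTA = 1 - 4/20 = 0.8
        gt = self.make_tracks(10, [(1, b(0, 0)), (2, b(50, 0))])
        hyp = {}
        for f in range(10):
            items = []
            if f not in (0, 1):          # two missed frames for pig 1
                items.append((1 if f < 9 else 9, b(0, 0)))  # id switch at f=9
            items.append((2, b(50, 0)))
            if f == 5:
                items.append((7, b(200, 0)))  # one false positive
            hyp[f] = items
        out = clearmot(gt, hyp)
        assert out.misses == 2 and out.false_positives == 1 and out.mismatches == 1
        assert out.mota == pytest.approx(0.8)

    def test_single_id_switch_two_pigs_twenty_frames(self):
        # hand-traced CLEAR accounting: 40 gt boxes, one mismatch -> 0.975
        gt = self.make_tracks(20, [(1, b(0, 0)), (2, b(100, 0))])
        hyp = {f: [(1 if f < 10 else 5, b(0, 0)), (2, b(100, 0))] for f in range(20)}
        out = clearmot(gt, hyp)
        assert out.mismatches == 1
        assert out.mota == pytest.approx(1 - 1 / 40)
        assert out.motp == pytest.approx(0.0)

    def test_motp_distance_form_bounded(self):
        gt = self.make_tracks(5, [(1, b(0, 0))])
        hyp = self.make_tracks(5, [(1, b(1, 1))])  # IOU 0.68, above threshold
        out = clearmot(gt, hyp)
        assert out.matches_total == 5
        assert 0.0 < out.motp <= 1.0
        pix = clearmot(gt, hyp, distance="pixel")
        assert pix.motp == pytest.approx(np.hypot(1, 1))

    def test_mota_invariant_under_frame_relabeling(self):
        gt = self.make_tracks(8, [(1, b(0, 0)), (2, b(60, 0))])
        hyp = {f: [(1, b(1, 0)), (2, b(61, 0))] for f in range(8)}
        a = clearmot(gt, hyp).mota
        gt2 = {f + 100: v for f, v in gt.items()}
        hyp2 = {f + 100: v for f, v in hyp.items()}
        assert clearmot(gt2, hyp2).mota == a


class TestCountingEval:
    def test_perfect(self):
        mae, r2 = counting_eval([10, 20, 30], [10, 20, 30])
        assert mae == 0.0 and r2 == 1.0

    def test_substitution(self):
        mae, r2 = counting_eval([10, 20, 30], [11, 19, 30])
        assert mae == pytest.approx(2.0 / 3.0)

    def test_constant_predictor_r2_zero(self):
        y = np.array([10.0, 20.0, 30.0])
        _, r2 = counting_eval(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_zero_variance_truths_flagged(self):
        mae, r2 = counting_eval([5, 5, 5], [5, 6, 5])
        assert np.isnan(r2) and mae == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            counting_eval([1, 2], [1])

    @given(st.lists(st.integers(0, 30), min_size=3, max_size=12))
    def test_matches_sklearn_on_random_vectors(self, y):
        from sklearn.metrics import mean_absolute_error, r2_score
        rng = np.random.default_rng(sum(y))
        yhat = np.asarray(y) + rng.integers(-3, 4, len(y))
        mae, r2 = counting_eval(y, yhat)
        assert mae == pytest.approx(mean_absolute_error(y, yhat))
        if np.var(y) > 0:
            assert r2 == pytest.approx(r2_score(y, yhat))
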