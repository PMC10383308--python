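"""Evaluate the tracker with CLEAR-MOT and the counter with MAE / R².

Runs the full pipeline on a jittery, lightly dropped-out scenario and
scores the hypothesis tracks against ground truth:

    MOTA = 1 - (misses + false positives + mismatches) / gt boxes
    MOTP = mean matched-pair distance (here 1 - IOU, so 0 is perfect)

then scores counting over a small scenario battery with the mean absolute
error and the coefficient of determination.
"""

from pigtrack import (DetectionNoise, IDCorrector, SimParams, Tracker,
                      TrackerConfig, clearmot, compute_stats, count_stream,
                      counting_eval, generate_scenario, oracle_detections)

params = SimParams(n_pigs=8, scale=0.25)
gt = generate_scenario(params, seed=18)
noise = DetectionNoise(jitter_sigma=1.5, dropout_p=0.02, with_features=True)
detections = oracle_detections(gt, noise, seed=18)
stats = compute_stats(gt.tracks())

tracker = Tracker(TrackerConfig())
corrector = IDCorrector(stats, gt.frame_width, horizon=30)
hypothesis = {}
for frame, dets in enumerate(detections):
    confirmed = tracker.step(dets, frame)
    corrector.observe(tracker, confirmed, frame)
    hypothesis[frame] = [(t.id, t.box) for t in confirmed]

res = clearmot(gt.frames, hypothesis)
print(f"MOTA {res.mota:.4f}  MOTP {res.motp:.4f}  "
      f"(misses {res.misses}, fp {res.false_positives}, "
      f"mismatches {res.mismatches}, gt boxes {res.gt_total})")

true_counts, predicted = [], []
for seed in range(30, 38):
    g = generate_scenario(SimParams(n_pigs=3 + seed % 6, scale=0.25), seed)
    d = oracle_detections(g, DetectionNoise(jitter_sigma=1.5), seed)
    r = count_stream(d, TrackerConfig(), compute_stats(g.tracks()),
                     frame_width=g.frame_width)
    true_counts.append(g.n_pigs)
    predicted.append(r.count)
mae, r2 = counting_eval(true_counts, predicted)
print(f"counting over 8 scenarios: true {true_counts} predicted {predicted}")
print(f"MAE {mae:.3f}  R^2 {r2:.4f}")
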