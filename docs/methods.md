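# Methods

## Problem setting and model

A fixed overhead camera films a 1.5 m-wide corridor at 25 fps,
2688 × 1520 px; pigs pass at normal walking speed (bounded by a 3 m/s
analogue, ≈ 122 px/frame at full scale). Counting is framed as
tracking-by-detection: per-frame boxes are associated into identities and
identities are counted under validity rules that encode two physical facts
about a corridor: (1) complete animals only enter and leave across the
left/right frame edges, so their pixel area is unimodal over a crossing
(grows, peaks, shrinks); (2) real crossings persist for many frames,
whereas identity fragments born of edge flicker or churn do not.

### Tracking substrate

Each track holds a constant-velocity Kalman state
`(cx, cy, γ, h, velocities)` with noise proportional to box height
(position std `h/20`, velocity std `h/160`). The aspect-ratio (γ) noise is
deliberately loose — process/measurement std `2e-2`, initial std `1e-1` —
because boxes clipped at the frame edge change aspect by ~0.2 per frame
while an animal enters or leaves; with the tight values used for
pedestrian tracking the filter cannot follow and association collapses at
the edges (this was measured, not assumed: entry churn disappeared once γ
could adapt).

Association is a cascade: confirmed tracks, most recently updated first,
match detections by the minimum cosine distance between the detection
embedding and the track's gallery (budget 100 features), admissible only
under the appearance gate (0.1) and a χ²(0.95, 4 dof) Mahalanobis gate on
the projected state; leftovers and tentative tracks fall back to IOU
matching (gate 0.5). Assignments are solved optimally
(`linear_sum_assignment`), ties broken by track id for determinism.
Detections are pre-filtered at confidence 0.5 and greedy IOU NMS 0.6.
Tracks confirm after 3 consecutive hits and die after `max_age = 30`
frames unmatched (≈ 1.2 s; corridor transit takes 2.5–5 s) — except in
breeding mode, where age-based deletion is disabled because pen residents
legitimately stay for the whole video.

One deliberate deviation from the reference cascade: a confirmed track
with an *empty* gallery (featureless operation, e.g. oracle detections
without embeddings) stays IOU-eligible at any staleness. Under the strict
reference rule such a track could never be re-matched at all, since only
the appearance stage considers stale tracks.

### Spatial-state ID correction

After each tracker step, newly seen identities are tested on their latest
*measured* box (the filtered state lags edge-clipped boxes): the
correction fires when `min(γh² − s/4, edge_distance − margin) > 0`, i.e.
area at least a quarter of the maximum single-animal detection area
(30,000 px² at the full-scale default `s = 120,000` px²) and full
horizontal containment (margin default 0; the vertical coordinate is
irrelevant under a corridor camera). Flagged newcomers are assigned the
Euclidean-nearest member of the lost pool, one-to-one and globally
optimal; the restored id is rewritten inside the tracker so it persists.

Lost-pool membership is the same predicate applied to disappearances: an
identity whose last box touched a horizontal edge (or never reached s/4)
exited normally and is *not* a tracking loss. Without this symmetry,
normally exiting animals polluted the pool and reborn tracks could
inherit the wrong identity (observed on seeded occlusion scenarios).
Lost entries are retained for `max_age` frames (shared default,
configurable); distances are plain center-to-center, no velocity
extrapolation, and no distance cap by default.

### Frame-number / area counting

Every corrected identity accumulates a ledger record
`(id, n, γ-history, h-history, center-x history)`. From reference
tracking data (ground-truth tracks in simulation, or config defaults
`z = 40`, `s = 120,000` px²) the rule computes `z` = mean track length
and `s` = maximum per-frame area, and counts a record once
`max γh² ≥ s/2` **and** `n ≥ z/2` (fractions configurable; the peak
rather than the latest area is used, since the peak is what "was fully
visible" means under the unimodal profile). Counted records move to a
second ledger. At stream end, each counted record's center-x series is
smoothed (moving average, window 5 frames) and scanned for direction
reversals exceeding a hysteresis of 10% of the frame width; a record with
at least one reversal that exits through its entry side nets zero
crossings and retracts one count. A cross–return–cross trajectory exits
the far side and keeps its single count. The smoothing window and
hysteresis reject 25 fps jitter; both are configurable.

### Re-identification embedding

The embedding network is: 3×3 conv (32 ch), 3×3/2 max pool, nine 3×3
residual layers (32, 64/2, 64, 64, 128/2, 128, 256/2, 256, 512/2;
pre-activation blocks, projection shortcuts on stride 2), batch-norm +
ReLU, global average pool → 512-d vector, L2-normalized. Crops are wide
(width : height = 2 : 1, default 128 × 64): pigs seen from above are
long, unlike upright pedestrians. The published layer table carries a
`512 × 4 × 1` final spatial size that is inconsistent with five stride-2
stages from any 2:1 input; the global average pool makes the contract
(512-d unit embedding) independent of that bookkeeping. Training is
softmax cross-entropy over identities through a linear head (SGD,
momentum 0.9, weight decay 5e-4, cosine learning-rate schedule, random
horizontal flips), stratified 80/20 split, accuracy = correct/total on
the held-out split per epoch; the head is discarded afterwards. The
network and its backprop run on a small numpy layer library
(`pigtrack.nn`) whose gradients are verified against finite differences
in the test suite.

### Detector-side operators

SoftPool returns `Σ wᵢaᵢ` with `wᵢ = e^{aᵢ}/Σ e^{aⱼ}` over each window,
computed with max-subtraction for stability; window padding is masked
(padded cells get zero softmax weight) rather than zero-filled, which
would bias edge windows. The SPP blocks concatenate the input with
stride-1 "same"-padded pooled copies at windows {1, 11, 13, 15} and
{1, 3, 5, 7} (odd sizes only, so symmetric padding exists), multiplying
the channel count by the branch count. The CIOU loss is
`1 − IOU + ρ²/c² + αv` with `v = (4/π²)(arctan w_t/h_t − arctan w_p/h_p)²`
and `α = v/((1−IOU)+v)`, defined as 0 at the 0/0 perfect-match corner.
These are standalone, testable operators; no full detector is trained
(the optional toy detector was omitted — no training framework for
convolutional detectors is available, and every operator contract is
covered by direct unit and property tests).

## Synthetic scenarios

The simulator emulates the study conditions: 2688 × 1520 @ 25 fps
geometry (scalable; the standard desk scale is 0.25 → 672 × 380 with all
area thresholds scaled by 1/16), pigs as moving body rectangles of
500–630 × 170–215 px (peak areas ≈ 85,000–135,000 px², consistent with a
120,000 px² maximum) whose ground-truth box is the body∩frame
intersection — giving the unimodal area profile by construction. Default
speeds are 25–50 px/frame (a 0.6–1.2 m/s walking analogue, under the
3 m/s cap, which the generator enforces). Entry sides get disjoint lane
bands so opposite streams never collide head-on; lanes reopen only after
the previous body clears the entry edge and followers never outrun
leaders, so clean scenarios contain no physically-impossible box
mergers. Crowding pairs walk side-by-side in adjacent lanes; turn-back
specs reverse a pig at a stated fraction of its crossing; breeding mode
wanders pigs inside a pen for a fixed duration. Everything is a
deterministic function of the seed.

The oracle detector emits each ground-truth box with probability `1 − p`,
center-jittered N(0, σ), confidence `max(0.5, 1 − |jitter|/h)`, plus
Poisson false positives, optional occlusion bursts (a named pig invisible
for a stretch of frames), and optional per-identity unit features with
Gaussian perturbation. The random stream is consumed identically for
every `p`, so the surviving-detection sets are nested across dropout
levels — robustness curves compare severities on the same realization,
not different luck. The renderer draws each pig as a textured ellipse
(per-identity gray level, color tint, spot pattern; per-crop pose and
noise variation) for embedding training.

What the simulator does *not* model: real coat appearance, deformation
and gait, detector-correlated errors (its noise is independent across
frames except for bursts), partial-body detections of the kind a real
detector produces, and lighting. Passing the batteries therefore shows
the tracking/correction/counting logic is correct under the stated error
model, not that any real detector reaches a particular accuracy.

## Standard batteries and problem sizes

All batteries (`pigtrack.experiments`) run at desk scale: 50 clean
scenarios of 2–15 pigs (the first four fixed at 2/3/4/5) for exactness;
20 scenarios with two 40-frame occlusion bursts each for the correction
ablation; 15 scenarios × severities p ∈ {0, 0.05, 0.1, 0.2} with
`round(20p)` bursts and σ = 2 px jitter for robustness; one edge-flicker
scenario (three 12-frame peeks separated by 40-frame gaps, then a
crossing); breeding pens of 2–5 pigs for 300 frames; and re-ID training
with width multiplier 0.25 on 64 × 32 crops of 10 identities × 30 crops,
12 epochs. These sizes are the package's standard desk-scale settings;
the full-scale geometry and the full 512-d network are exercised by the
structural checks and remain available via `scale=1.0` /
`ReIDSpec()`.

## Numerical and degenerate-input choices

Boxes require positive height and aspect; zero-area boxes are contract
violations. The correction predicate is strictly positive with a 1e-6 px
tolerance so boxes clipped *exactly* at the edge (edge distance 0 up to
float round-trip noise) are never treated as interior. R² is NaN for
zero-variance truths (flagged undefined, not an exception, since MAE is
still meaningful). MOTP defaults to the bounded `1 − IOU` distance; a
pixel-center mode exists because the printed convention in this problem
area is ambiguous. CLEAR matching persists previous-frame
correspondences while they still clear the IOU threshold and solves the
rest optimally. AP uses all-points interpolation of the precision
envelope. Kalman covariance is re-symmetrized after updates.

## Known limitations

Counting accuracy under heavy noise degrades with dropout severity by
design (the robustness battery documents the curve); bursts that swallow
the remainder of a fast crossing are unrecoverable by any spatial rule.
The nearest-lost assignment is purely spatial (per the method), so
simultaneous multi-pig losses can be re-linked to the wrong neighbor.
The turn-back rule assumes a single dominant travel axis and is disabled
in breeding mode. The re-ID renderer's identities are easier to separate
than real pigs; its accuracy numbers calibrate the training loop, not
field performance.
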