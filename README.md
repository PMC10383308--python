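# pigtrack

Tracking-by-detection pig counting from a single overhead camera.

Counting pigs as they move through a slaughterhouse aisle (or live in a
breeding pen) is usually done by hand: slow, error-prone, and stressful
for the animals. With one camera above the corridor, the problem becomes
multi-object tracking — but a naive "count the track identities" rule
fails badly, because animals that move fast, squeeze each other, or
flicker at the frame edge constantly break their tracks and acquire new
identities. `pigtrack` implements a counting pipeline that is robust to
exactly those failures, together with a synthetic corridor simulator and
a full evaluation suite, so every stage can be developed and tested
without farm footage.

## The method

Per-frame detections (from any detector) feed an appearance-aided Kalman
tracker over the 8-dimensional state `(u, v, γ, h, u̇, v̇, γ̇, ḣ)` — box
center, aspect ratio `γ = w/h`, height, and their velocities. Association
cascades from appearance (cosine distance between 512-d re-identification
embeddings and each track's feature gallery, gated by a χ²(0.95, 4 dof)
Mahalanobis test) to IOU fallback, with optimal bipartite assignment.
Two corridor-specific rules sit on top:

* **Spatial-state ID correction.** In a corridor, a complete animal
  cannot materialize mid-frame; it can only enter across the left/right
  edges, its pixel area growing from zero. So a *newly born* identity
  whose box area `γh²` already exceeds one quarter of the maximum
  single-animal detection area `s` (30,000 px² for the default
  `s = 120,000` px²) *and* lies fully inside the frame horizontally must
  be a lost track reborn — it inherits the Euclidean-nearest recently
  lost identity instead of inflating the id count.

* **Frame-number / area counting.** An identity is counted only once it
  has appeared in at least `z/2` frames (`z` = average track length of
  the reference tracking data) *and* reached a peak area of at least
  `s/2` — i.e. it persisted like a real crossing and was fully visible
  at some point. Identities that flicker at the edge never qualify.
  Counted animals whose smoothed center-x trajectory reverses direction
  and exits through the entry side are retracted (turn-backs).

The package also provides the detector-side operators (SoftPool —
softmax-weighted window pooling, two spatial-pyramid-pooling blocks with
windows 1/11/13/15 and 1/3/5/7, and the complete-IOU loss), the
residual re-identification network (one conv, one max pool, nine residual
layers, average pool → unit-norm 512-d embedding, trained on 2:1-wide
crops), a deterministic corridor/pen simulator with an explicit detection
noise model, and the metric suite (precision/recall/AP/mAP, accuracy,
CLEAR-MOT MOTA/MOTP, counting MAE and R²).

## Worked example

`python examples/02_id_correction.py` — a pig is occluded for 40 frames
mid-corridor (longer than the tracker's 30-frame `max_age`, so its track
dies and it is reborn as a fresh interior identity):

```
5 pigs; occlusion burst: pig 2 hidden frames 50-89
with correction   : count 5 (truth 5), 5 distinct ids, remaps: id 11->6 at frame 92
without correction: count 4 (truth 5), 6 distinct ids, remaps: none
```

With the correction, the reborn track (id 11) inherits the lost id 6 at
frame 92; the merged record passes both counting conditions and the count
is exact. Without it, the crossing splits into two short records, neither
of which persists `z/2` frames, and the pig is missed. The other examples
cover edge-flicker overcounting (`03`), turn-backs (`04`), CLEAR-MOT and
counting evaluation (`05`), re-ID training (`06`) and the pooling/loss
operators (`07`).

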