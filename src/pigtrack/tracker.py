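"""Appearance-aided multi-object tracker (tracking-by-detection).

The substrate is the classic two-stage design: a constant-velocity Kalman
filter per track, cascade matching that associates recently seen tracks
first using cosine distance between detection embeddings and the track's
feature gallery (gated by a Mahalanobis test on the predicted state), and an
IOU-based fallback for tracks and detections the appearance stage left
unmatched.  Track lifecycle: tentative until ``n_init`` consecutive hits,
then confirmed; deleted after ``max_age`` frames without a match ("aisle"
mode).  In "breeding" mode — pens where animals stay in view indefinitely —
age-based deletion is disabled so a long-lived identity is never dropped.

Detections without appearance features (e.g. oracle detections from the
simulator) fall back to pure IOU association.
"""

from __future__ import annotations

import enum
import itertools
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import Box, iou
from .kalman import CHI2_95_4DOF, KalmanFilter

__all__ = ["Detection", "TrackStatus", "Track", "TrackerConfig", "Tracker",
           "associate", "nms"]

INF_COST = 1e5


@dataclass(frozen=True)
class Detection:
    """A single-frame detector output."""

    box: Box
    confidence: float = 1.0
    feature: np.ndarray | None = None
    frame: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


class Track:
    """One tracked animal: Kalman state, lifecycle counters, feature gallery."""

    def __init__(self, track_id: int, kf: KalmanFilter, detection: Detection,
                 n_init: int, gallery_budget: int):
        self.id = track_id
        self._kf = kf
        meas = np.array([detection.box.cx, detection.box.cy,
                         detection.box.gamma, detection.box.h])
        self.mean, self.covariance = kf.initiate(meas)
        self.hits = 1
        self.age = 1
        self.time_since_update = 0
        self.last_detection: Box = detection.box
        self._n_init = n_init
        self.status = TrackStatus.CONFIRMED if n_init <= 1 else TrackStatus.TENTATIVE
        self.gallery: deque[np.ndarray] = deque(maxlen=gallery_budget)
        if detection.feature is not None:
            self.gallery.append(np.asarray(detection.feature, dtype=np.float32))

    @property
    def box(self) -> Box:
        cx, cy, g, h = self.mean[:4]
        return Box(cx, cy, max(g, 1e-6), max(h, 1e-6))

    def predict(self) -> None:
        self.mean, self.covariance = self._kf.predict(self.mean, self.covariance)
        self.age += 1
        self.time_since_update += 1

    def update(self, detection: Detection) -> None:
        meas = np.array([detection.box.cx, detection.box.cy,
                         detection.box.gamma, detection.box.h])
        self.mean, self.covariance = self._kf.update(self.mean, self.covariance, meas)
        self.hits += 1
        self.time_since_update = 0
        self.last_detection = detection.box
        if detection.feature is not None:
            self.gallery.append(np.asarray(detection.feature, dtype=np.float32))
        if self.status is TrackStatus.TENTATIVE and self.hits >= self._n_init:
            self.status = TrackStatus.CONFIRMED

    def mark_missed(self, max_age: int, breeding: bool) -> None:
        if self.status is TrackStatus.TENTATIVE:
            self.status = TrackStatus.DELETED
        elif not breeding and self.time_since_update > max_age:
            self.status = TrackStatus.DELETED


@dataclass
class TrackerConfig:
    """Tracker parameters; the matching-stage defaults follow the published
    configuration (appearance gate 0.1, confidence floor 0.5, NMS 0.6, IOU
    gate 0.5)."""

    max_dist: float = 0.1
    min_confidence: float = 0.5
    nms_max_overlap: float = 0.6
    max_iou_distance: float = 0.5
    max_age: int = 30
    n_init: int = 3
    gallery_budget: int = 100
    mode: str = "aisle"

    def __post_init__(self) -> None:
        if self.mode not in ("aisle", "breeding"):
            raise ValueError(f"mode must be 'aisle' or 'breeding', got {self.mode!r}")


def nms(detections: list[Detection], max_overlap: float) -> list[Detection]:
    """Greedy non-maximum suppression by confidence at an IOU threshold."""
    if max_overlap >= 1.0:
        return list(detections)
    order = sorted(range(len(detections)), key=lambda i: -detections[i].confidence)
    keep: list[int] = []
    for i in order:
        if all(iou(detections[i].box, detections[j].box) <= max_overlap for j in keep):
            keep.append(i)
    return [detections[i] for i in sorted(keep)]


def _gallery_cost(track: Track, det: Detection) -> float:
    if det.feature is None or not track.gallery:
        return np.inf
    g = np.stack(track.gallery)
    f = np.asarray(det.feature, dtype=np.float32)
    g = g / np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-12)
    f = f / max(np.linalg.norm(f), 1e-12)
    return float((1.0 - g @ f).min())


def _solve(cost: np.ndarray) -> list[tuple[int, int]]:
    """Min-cost assignment keeping only admissible (finite-cost) pairs."""
    if cost.size == 0:
        return []
    rows, cols = linear_sum_assignment(cost)
    return [(r, c) for r, c in zip(rows, cols) if cost[r, c] < INF_COST]


def associate(tracks: list[Track], detections: list[Detection],
              config: TrackerConfig, kf: KalmanFilter | None = None,
              ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match tracks to detections; returns (matches, unmatched tracks,
    unmatched detections) as indices into the input lists.

    Stage 1 (appearance cascade): confirmed tracks, most recently updated
    first; cost is the minimum cosine distance between the detection feature
    and the track gallery, admissible only under both the appearance gate
    and the chi-square Mahalanobis gate.  Stage 2 (IOU): tentative tracks
    plus stage-1 leftovers that missed at most one frame, matched by IOU.
    Tracks are processed in id order so ties resolve deterministically.
    """
    matches: list[tuple[int, int]] = []
    unmatched_dets = list(range(len(detections)))

    confirmed = sorted((i for i, t in enumerate(tracks) if t.status is TrackStatus.CONFIRMED),
                       key=lambda i: tracks[i].id)
    others = sorted((i for i, t in enumerate(tracks) if t.status is not TrackStatus.CONFIRMED),
                    key=lambda i: tracks[i].id)

    meas = np.array([[d.box.cx, d.box.cy, d.box.gamma, d.box.h] for d in detections]
                    ) if detections else np.zeros((0, 4))

    # appearance cascade over staleness
    unmatched_confirmed: list[int] = []
    if confirmed and detections:
        for _, group in itertools.groupby(
                sorted(confirmed, key=lambda i: (tracks[i].time_since_update, tracks[i].id)),
                key=lambda i: tracks[i].time_since_update):
            grp = list(group)
            if not unmatched_dets:
                unmatched_confirmed.extend(grp)
                continue
            cost = np.full((len(grp), len(unmatched_dets)), INF_COST)
            for r, ti in enumerate(grp):
                t = tracks[ti]
                gate = t._kf.gating_distance(t.mean, t.covariance,
                                             meas[unmatched_dets])
                for c, di in enumerate(unmatched_dets):
                    ac = _gallery_cost(t, detections[di])
                    if np.isfinite(ac) and ac <= config.max_dist and gate[c] <= CHI2_95_4DOF:
                        cost[r, c] = ac
            got = _solve(cost)
            matched_cols = set()
            for r, c in got:
                matches.append((grp[r], unmatched_dets[c]))
                matched_cols.add(c)
            unmatched_confirmed.extend(grp[r] for r in range(len(grp))
                                       if r not in {g[0] for g in got})
            unmatched_dets = [d for c, d in enumerate(unmatched_dets) if c not in matched_cols]
    else:
        unmatched_confirmed = list(confirmed)

    # IOU fallback: tentative tracks + freshly missed confirmed tracks.
    # Confirmed tracks without any appearance gallery (featureless
    # operation) can never be recovered by the cascade, so they stay
    # IOU-eligible however stale they are.
    iou_tracks = sorted(others + [i for i in unmatched_confirmed
                                  if tracks[i].time_since_update <= 1
                                  or not tracks[i].gallery],
                        key=lambda i: tracks[i].id)
    stale = [i for i in unmatched_confirmed
             if tracks[i].time_since_update > 1 and tracks[i].gallery]
    if iou_tracks and unmatched_dets:
        cost = np.full((len(iou_tracks), len(unmatched_dets)), INF_COST)
        for r, ti in enumerate(iou_tracks):
            for c, di in enumerate(unmatched_dets):
                d = 1.0 - iou(tracks[ti].box, detections[di].box)
                if d <= config.max_iou_distance:
                    cost[r, c] = d
        got = _solve(cost)
        matched_cols = set()
        for r, c in got:
            matches.append((iou_tracks[r], unmatched_dets[c]))
            matched_cols.add(c)
        unmatched_tracks = stale + [iou_tracks[r] for r in range(len(iou_tracks))
                                    if r not in {g[0] for g in got}]
        unmatched_dets = [d for c, d in enumerate(unmatched_dets) if c not in matched_cols]
    else:
        unmatched_tracks = stale + iou_tracks

    return matches, sorted(unmatched_tracks), unmatched_dets


class Tracker:
    """Frame-by-frame multi-object tracker with strictly increasing ids."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.kf = KalmanFilter()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def _new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def drop_track(self, track_id: int) -> None:
        """Remove a live track (used when a stale track's identity has been
        handed to its reborn successor)."""
        self.tracks = [t for t in self.tracks if t.id != track_id]

    def rename_track(self, current_id: int, restored_id: int) -> None:
        """Give a track back a previously lost identity (ID correction)."""
        for t in self.tracks:
            if t.id == current_id:
                t.id = restored_id
                return
        raise KeyError(f"no live track with id {current_id}")

    def step(self, detections: list[Detection], frame: int) -> list[Track]:
        """Advance one frame; returns the confirmed tracks that matched a
        detection this frame (plus just-confirmed ones)."""
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(f"frames must be processed in increasing order "
                             f"(got {frame} after {self._last_frame})")
        self._last_frame = frame

        dets = [d for d in detections if d.confidence >= self.config.min_confidence]
        dets = nms(dets, self.config.nms_max_overlap)

        for t in self.tracks:
            t.predict()

        matches, unmatched_tracks, unmatched_dets = associate(
            self.tracks, dets, self.config, self.kf)

        for ti, di in matches:
            self.tracks[ti].update(dets[di])
        breeding = self.config.mode == "breeding"
        for ti in unmatched_tracks:
            self.tracks[ti].mark_missed(self.config.max_age, breeding)
        for di in unmatched_dets:
            self.tracks.append(Track(self._new_id(), self.kf, dets[di],
                                     self.config.n_init, self.config.gallery_budget))
        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]
        return [t for t in self.tracks
                if t.status is TrackStatus.CONFIRMED and t.time_since_update == 0]
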