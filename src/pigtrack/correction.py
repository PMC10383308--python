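"""Spatial-state ID correction.

In a corridor filmed from above, a complete animal cannot materialize in
the middle of the frame: bodies enter and leave only across the left/right
frame edges, growing and then shrinking in pixel area as they do.  So when
the tracker confirms a *new* identity whose box is already near-complete
(area at least one quarter of the maximum single-animal detection area,
30,000 px² for the default 120,000 px²) and lies fully inside the frame
horizontally, that identity must really be a previously tracked animal
whose track was lost — typically after a fast move or a long occlusion.
The correction finds the Euclidean-nearest recently lost identity and gives
it back to the new track, so downstream counting sees one animal, not two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import Box
from .tracker import Track, Tracker

__all__ = ["CountingStats", "CorrectionDiagnostic", "RemapEvent",
           "classify_frame_changes", "needs_correction", "correct_ids",
           "IDCorrector"]


@dataclass(frozen=True)
class CountingStats:
    """Population statistics driving the correction and counting rules.

    ``s`` is the maximum single-animal detection area (px²) and ``z`` the
    average track length in frames, both estimated from a tracking dataset
    (or taken from config defaults).  The entry threshold — the area above
    which an animal counts as "complete" — is s/4.  ``area_frac`` and
    ``frame_frac`` are the validity fractions used by the counting rule.
    """

    s: float = 120_000.0
    z: float = 40.0
    area_frac: float = 0.5
    frame_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.s <= 0 or self.z <= 0:
            raise ValueError("s and z must be positive")

    @property
    def enter_threshold(self) -> float:
        return self.s / 4.0

    def scaled(self, scale: float) -> "CountingStats":
        """Stats for a frame downscaled by ``scale`` (areas scale by scale²)."""
        return CountingStats(self.s * scale * scale, self.z,
                             self.area_frac, self.frame_frac)


@dataclass(frozen=True)
class CorrectionDiagnostic:
    """Why a newly born identity was (or was not) flagged for correction.

    ``r_value`` is the signed margin ``min(area - s/4, edge_distance -
    margin)``: positive exactly when the box is both near-complete and
    interior.  ``remap`` is filled in once a lost identity has been
    assigned.
    """

    r_value: float
    area: float
    edge_distance: float
    remap: tuple[int, int] | None = None

    @property
    def flagged(self) -> bool:
        # strictly interior; the tolerance absorbs float noise in boxes
        # clipped exactly at the frame edge
        return self.r_value > 1e-6


@dataclass(frozen=True)
class RemapEvent:
    frame: int
    new_id: int
    restored_id: int
    distance: float


def classify_frame_changes(prev_tracks: list[tuple[int, Box]],
                           curr_tracks: list[tuple[int, Box]],
                           ) -> tuple[set[int], dict[int, Box]]:
    """Identities that appeared and disappeared between consecutive frames.

    Returns ``(new_ids, lost)`` where ``lost`` maps each vanished id to its
    last known box.
    """
    prev = dict(prev_tracks)
    curr = dict(curr_tracks)
    new_ids = set(curr) - set(prev)
    lost = {i: b for i, b in prev.items() if i not in curr}
    return new_ids, lost


def needs_correction(box: Box, frame_width: float, stats: CountingStats,
                     margin: float = 0.0) -> CorrectionDiagnostic:
    """Interior, near-complete test for a newly born identity's box.

    Positive ``r_value`` iff the box area (gamma * h²) reaches the entry
    threshold s/4 *and* the box lies fully inside the frame horizontally
    (with an optional extra pixel margin).  Only the horizontal coordinate
    is tested: the corridor runs left-right under the camera.
    """
    if frame_width <= 0:
        raise ValueError("frame_width must be positive")
    half_w = box.w / 2.0
    edge_distance = min(box.cx - half_w, frame_width - box.cx - half_w)
    r = min(box.area - stats.enter_threshold, edge_distance - margin)
    return CorrectionDiagnostic(r_value=r, area=box.area, edge_distance=edge_distance)


def correct_ids(new_tracks: dict[int, Box], lost_tracks: dict[int, Box],
                max_distance: float | None = None) -> dict[int, int]:
    """Assign each flagged new identity the nearest lost identity.

    Globally optimal (minimum total center-to-center Euclidean distance)
    one-to-one pairing: no lost id is handed to two new tracks.  New ids
    without any available lost id keep their own id (absent from the
    returned mapping).
    """
    if not new_tracks or not lost_tracks:
        return {}
    new_ids = sorted(new_tracks)
    lost_ids = sorted(lost_tracks)
    cost = np.zeros((len(new_ids), len(lost_ids)))
    for r, ni in enumerate(new_ids):
        nb = new_tracks[ni]
        for c, li in enumerate(lost_ids):
            lb = lost_tracks[li]
            cost[r, c] = np.hypot(nb.cx - lb.cx, nb.cy - lb.cy)
    rows, cols = linear_sum_assignment(cost)
    remap = {}
    for r, c in zip(rows, cols):
        if max_distance is None or cost[r, c] <= max_distance:
            remap[new_ids[r]] = lost_ids[c]
    return remap


class IDCorrector:
    """Streaming ID correction over a tracker's confirmed output.

    Call :meth:`observe` once per frame, after the tracker step and before
    any counting.  Maintains the pool of recently lost identities (retained
    for ``horizon`` frames), flags interior near-complete newborn ids, and
    rewrites their identity both in the returned track list and inside the
    tracker so the restored id persists.
    """

    def __init__(self, stats: CountingStats, frame_width: float,
                 horizon: int = 30, margin: float = 0.0,
                 max_distance: float | None = None):
        self.stats = stats
        self.frame_width = frame_width
        self.horizon = horizon
        self.margin = margin
        self.max_distance = max_distance
        self._seen: set[int] = set()
        self._last_box: dict[int, Box] = {}
        self._lost: dict[int, tuple[Box, int]] = {}  # id -> (last box, frames since lost)
        self.events: list[RemapEvent] = []

    def observe(self, tracker: Tracker, confirmed: list[Track],
                frame: int) -> list[RemapEvent]:
        curr_ids = {t.id for t in confirmed}

        # age the lost pool; resurface ids that came back on their own
        for lid in list(self._lost):
            if lid in curr_ids:
                del self._lost[lid]
            else:
                box, since = self._lost[lid]
                if since + 1 > self.horizon:
                    del self._lost[lid]
                else:
                    self._lost[lid] = (box, since + 1)
        for sid in self._seen - curr_ids:
            if sid not in self._lost and sid in self._last_box:
                # symmetric to the birth rule: a disappearance at the frame
                # edge is an exit, not a tracking loss — only interior,
                # near-complete disappearances join the lost pool
                last = self._last_box[sid]
                if needs_correction(last, self.frame_width, self.stats,
                                    self.margin).flagged:
                    self._lost[sid] = (last, 0)

        # flag interior near-complete newcomers
        flagged: dict[int, Box] = {}
        for t in confirmed:
            if t.id in self._seen:
                continue
            # test the measured detection box, not the filtered state: the
            # filter lags the fast-changing shape of an edge-clipped box
            box = getattr(t, "last_detection", None) or t.box
            diag = needs_correction(box, self.frame_width, self.stats, self.margin)
            if diag.flagged:
                flagged[t.id] = box

        events: list[RemapEvent] = []
        if flagged and self._lost:
            lost_boxes = {i: b for i, (b, _) in self._lost.items()}
            remap = correct_ids(flagged, lost_boxes, self.max_distance)
            for new_id, old_id in sorted(remap.items()):
                # a stale track may still hold the lost id; retire it first
                for live in tracker.tracks:
                    if live.id == old_id:
                        tracker.drop_track(old_id)
                        break
                tracker.rename_track(new_id, old_id)
                d = float(np.hypot(flagged[new_id].cx - lost_boxes[old_id].cx,
                                   flagged[new_id].cy - lost_boxes[old_id].cy))
                events.append(RemapEvent(frame, new_id, old_id, d))
                del self._lost[old_id]

        curr_ids = {t.id for t in confirmed}  # ids after renaming
        self._seen |= curr_ids
        for t in confirmed:
            self._last_box[t.id] = t.box
        for lid in curr_ids:
            self._lost.pop(lid, None)
        self.events.extend(events)
        return events
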