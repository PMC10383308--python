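"""Frame-number / detection-area counting with turn-back adjustment.

An animal walking through the corridor grows in pixel area as it enters,
peaks, and shrinks as it leaves.  Identities that merely flicker at a frame
edge (few frames, small area) are tracker artifacts, not animals.  The
counting rule therefore keeps a ledger of every corrected identity —
``List(id, n, gamma, h, v)`` with n the number of distinct frames the id
appeared in and v its chronological center-x — and counts an identity only
once it has both (a) reached a peak area of at least ``area_frac * s`` and
(b) persisted for at least ``frame_frac * z`` frames, where s is the
maximum single-animal detection area and z the average track length of the
reference tracking data (default fractions 1/2).  Counted identities move
to ``List1(id, n, v)``.

Finally, the center-x history of each counted identity is checked for
turn-backs: an animal that penetrated the corridor but reversed direction
(beyond a smoothing-and-hysteresis threshold) and exited through the side
it entered never actually passed, so its count is retracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import Box
from .correction import CountingStats, IDCorrector, RemapEvent
from .tracker import Detection, Tracker, TrackerConfig

__all__ = ["TrackRecord", "CountDecision", "TurnbackEvent", "AuditEvent",
           "CountState", "CountResult", "update_records", "compute_stats",
           "valid_count", "detect_turnback", "count_stream"]


@dataclass
class TrackRecord:
    """Per-identity history: the counting ledger's List(id, n, gamma, h, v)."""

    id: int
    frames: list[int] = field(default_factory=list)
    gammas: list[float] = field(default_factory=list)
    hs: list[float] = field(default_factory=list)
    v_series: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.frames)

    @property
    def max_area(self) -> float:
        if not self.frames:
            return 0.0
        g = np.asarray(self.gammas)
        h = np.asarray(self.hs)
        return float((g * h * h).max())

    def append(self, frame: int, box: Box) -> None:
        self.frames.append(frame)
        self.gammas.append(box.gamma)
        self.hs.append(box.h)
        self.v_series.append(box.cx)


def update_records(records: dict[int, TrackRecord],
                   tracks: list[tuple[int, Box]], frame: int) -> dict[int, TrackRecord]:
    """Append this frame's corrected tracks to the ledger (in place)."""
    seen_this_frame: set[int] = set()
    for tid, box in tracks:
        if tid in seen_this_frame:
            raise ValueError(f"id {tid} appears twice in frame {frame}")
        seen_this_frame.add(tid)
        rec = records.setdefault(tid, TrackRecord(tid))
        if rec.frames and rec.frames[-1] == frame:
            raise ValueError(f"id {tid} already recorded for frame {frame}")
        rec.append(frame, box)
    return records


def compute_stats(tracks: list[list[Box]] | dict[int, TrackRecord],
                  area_frac: float = 0.5, frame_frac: float = 0.5) -> CountingStats:
    """Average track length z and maximum detection area s of a tracking
    dataset (ground-truth tracks or an existing ledger)."""
    values = list(tracks.values()) if isinstance(tracks, dict) else list(tracks)
    if values and isinstance(values[0], TrackRecord):
        lengths = [r.n for r in values]
        max_area = max((r.max_area for r in values), default=0.0)
    else:
        lengths = [len(t) for t in values]
        max_area = max((b.area for t in values for b in t), default=0.0)
    if not lengths or max_area <= 0:
        raise ValueError("tracking dataset must contain at least one non-empty track")
    return CountingStats(s=max_area, z=float(np.mean(lengths)),
                         area_frac=area_frac, frame_frac=frame_frac)


@dataclass(frozen=True)
class CountDecision:
    """Validity test outcome with its two signed margins (px² and frames)."""

    counted: bool
    area_margin: float
    frame_margin: float


def valid_count(record: TrackRecord, stats: CountingStats) -> CountDecision:
    """Should this identity be counted as a real animal?

    Positive exactly when the record's peak area reaches ``area_frac * s``
    (the animal was fully visible at some point) and its frame count
    reaches ``frame_frac * z`` (it persisted like a real crossing, not an
    edge flicker).
    """
    if record.n == 0:
        raise ValueError("empty record")
    area_margin = record.max_area - stats.area_frac * stats.s
    frame_margin = record.n - stats.frame_frac * stats.z
    return CountDecision(counted=(area_margin >= 0 and frame_margin >= 0),
                         area_margin=area_margin, frame_margin=frame_margin)


@dataclass(frozen=True)
class TurnbackEvent:
    id: int
    reversals: int
    entry_side: str
    exit_side: str


def _smooth(v: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or v.size <= k:
        return v
    kernel = np.ones(k) / k
    return np.convolve(v, kernel, mode="valid")


def _count_reversals(s: np.ndarray, hysteresis: float) -> int:
    """Direction changes of amplitude >= hysteresis in a 1-D series."""
    if s.size < 2:
        return 0
    reversals = 0
    direction = 0
    extreme = s[0]
    for x in s[1:]:
        if direction == 0:
            if x - extreme >= hysteresis:
                direction = 1
                extreme = x
            elif extreme - x >= hysteresis:
                direction = -1
                extreme = x
            else:
                continue
        elif direction == 1:
            if x > extreme:
                extreme = x
            elif extreme - x >= hysteresis:
                reversals += 1
                direction = -1
                extreme = x
        else:
            if x < extreme:
                extreme = x
            elif x - extreme >= hysteresis:
                reversals += 1
                direction = 1
                extreme = x
    return reversals


def detect_turnback(record: TrackRecord, frame_width: float,
                    smooth_window: int = 5, hysteresis_frac: float = 0.1,
                    ) -> list[TurnbackEvent]:
    """Turn-back events for a counted identity.

    The center-x series is smoothed with a moving average (window
    ``smooth_window`` frames) to reject per-frame jitter; a completed
    turn-back requires at least one direction reversal exceeding the
    hysteresis (default 10% of the frame width) *and* exit through the
    entry side.  Each completed turn-back retracts one count.
    """
    v = _smooth(np.asarray(record.v_series, dtype=float), smooth_window)
    if v.size == 0:
        return []
    hysteresis = hysteresis_frac * frame_width
    entry = "left" if v[0] < frame_width / 2.0 else "right"
    exit_ = "left" if v[-1] < frame_width / 2.0 else "right"
    reversals = _count_reversals(v, hysteresis)
    if reversals >= 1 and entry == exit_:
        return [TurnbackEvent(record.id, reversals, entry, exit_)]
    return []


@dataclass(frozen=True)
class AuditEvent:
    frame: int
    id: int
    event: str  # new | remap | counted | turnback
    count: int


@dataclass
class CountState:
    """Running counting state: List1 plus the turn-back adjustment."""

    counted: dict[int, TrackRecord] = field(default_factory=dict)
    turnback_adjustments: int = 0

    @property
    def count(self) -> int:
        return max(0, len(self.counted) - self.turnback_adjustments)


@dataclass
class CountResult:
    state: CountState
    per_frame_counts: list[tuple[int, int]]
    audit: list[AuditEvent]
    records: dict[int, TrackRecord]
    remap_events: list[RemapEvent]
    distinct_ids: set[int]

    @property
    def count(self) -> int:
        return self.state.count


def count_stream(frames: list[list[Detection]] | list[tuple[int, list[Detection]]],
                 config: TrackerConfig | None = None,
                 stats: CountingStats | None = None,
                 frame_width: float = 2688.0,
                 enable_correction: bool = True,
                 enable_turnback: bool = True,
                 correction_horizon: int | None = None,
                 smooth_window: int = 5,
                 hysteresis_frac: float = 0.1) -> CountResult:
    """Run the full pipeline: track -> correct ids -> ledger -> count.

    ``frames`` is either a list of per-frame detection lists (frame indices
    0..T-1) or explicit ``(frame_index, detections)`` pairs in increasing
    order.  Turn-back adjustment applies in aisle mode only (animals in a
    breeding pen never exit, so the rule is moot there).
    """
    config = config or TrackerConfig()
    stats = stats or CountingStats()
    tracker = Tracker(config)
    horizon = config.max_age if correction_horizon is None else correction_horizon
    corrector = IDCorrector(stats, frame_width, horizon=horizon) if enable_correction else None

    records: dict[int, TrackRecord] = {}
    state = CountState()
    audit: list[AuditEvent] = []
    per_frame: list[tuple[int, int]] = []
    distinct: set[int] = set()

    if frames and isinstance(frames[0], tuple):
        items = [(int(f), list(d)) for f, d in frames]
    else:
        items = [(i, list(d)) for i, d in enumerate(frames)]

    for frame, dets in items:
        confirmed = tracker.step(dets, frame)
        if corrector is not None:
            for ev in corrector.observe(tracker, confirmed, frame):
                audit.append(AuditEvent(frame, ev.new_id, "remap", state.count))
        for t in confirmed:
            if t.id not in distinct:
                distinct.add(t.id)
                audit.append(AuditEvent(frame, t.id, "new", state.count))
        update_records(records, [(t.id, t.box) for t in confirmed], frame)
        for tid, rec in records.items():
            if tid in state.counted:
                continue
            if valid_count(rec, stats).counted:
                state.counted[tid] = rec
                audit.append(AuditEvent(frame, tid, "counted", state.count))
        per_frame.append((frame, state.count))

    if enable_turnback and config.mode == "aisle":
        for tid in sorted(state.counted):
            events = detect_turnback(records[tid], frame_width,
                                     smooth_window, hysteresis_frac)
            for _ in events:
                state.turnback_adjustments += 1
                last_frame = items[-1][0] if items else 0
                audit.append(AuditEvent(last_frame, tid, "turnback", state.count))

    remaps = corrector.events if corrector is not None else []
    return CountResult(state=state, per_frame_counts=per_frame, audit=audit,
                       records=records, remap_events=remaps, distinct_ids=distinct)
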