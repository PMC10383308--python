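"""Synthetic corridor and pen scenarios with exact ground truth.

The generator emulates the study conditions the real videos were filmed
under: an overhead camera over a 1.5 m corridor, 25 fps, 2688 x 1520 frames,
animals entering and exiting only across the left/right frame edges at
bounded speed (at most a 3 m/s analogue, about 120 px/frame at full scale).
A pig is a moving body rectangle; its ground-truth box is the intersection
of the body with the frame, so the box area grows as the animal enters,
peaks when fully visible and shrinks as it leaves — the unimodal area
profile the counting rule relies on.

Everything is deterministic given the seed.  ``scale`` shrinks the whole
geometry (default desk scale 0.25 -> 672 x 380 frames) with areas scaling
by scale²; the analysis thresholds must be scaled consistently
(``CountingStats.scaled``).

``oracle_detections`` corrupts the ground truth with a stated noise model:
i.i.d. per-box dropout, burst dropouts (a pig invisible for a stretch of
frames, as under occlusion), Gaussian center jitter, Poisson false
positives, and optional per-identity appearance features.  The random
stream is consumed identically for every dropout probability, so raising p
only ever removes detections (nested noise — useful for robustness
curves).

``render_crops`` / ``render_frames`` draw pigs as textured ellipses (per
identity: coat gray level, color tint and spot pattern) for training the
re-identification embedding at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .boxes import Box
from .tracker import Detection

__all__ = ["SimParams", "TurnbackSpec", "Burst", "DetectionNoise", "PigTruth",
           "GroundTruth", "generate_scenario", "oracle_detections",
           "make_bursts", "texture_params", "render_crops", "render_frames"]

FULL_WIDTH, FULL_HEIGHT = 2688, 1520
PX_PER_M = FULL_HEIGHT / 1.5          # corridor width 1.5 m spans the frame height
MAX_SPEED_PX = 3.0 * PX_PER_M / 25.0  # 3 m/s at 25 fps ~ 121.6 px/frame


@dataclass(frozen=True)
class TurnbackSpec:
    """Reverse pig ``pig_index`` when it reaches ``at_progress`` of its
    crossing; optionally reverse again on the way back at
    ``again_at_progress`` (making it finish the crossing)."""

    pig_index: int
    at_progress: float = 0.6
    again_at_progress: float | None = None


@dataclass(frozen=True)
class SimParams:
    """Scenario parameters, full-scale pixels unless noted."""

    n_pigs: int = 5
    frame_width: float = FULL_WIDTH
    frame_height: float = FULL_HEIGHT
    fps: int = 25
    scale: float = 1.0
    mode: str = "aisle"
    speed_range: tuple[float, float] = (25.0, 50.0)       # px/frame, <= 3 m/s analogue
    body_len_range: tuple[float, float] = (500.0, 630.0)  # px along the corridor
    body_h_range: tuple[float, float] = (170.0, 215.0)    # px across the corridor
    entry_gap_range: tuple[int, int] = (10, 25)           # frames between entries per side
    duration: int | None = None                           # frames; auto for aisle
    turnbacks: tuple[TurnbackSpec, ...] = ()
    crowding_pairs: int = 0
    wander_speed_range: tuple[float, float] = (8.0, 20.0)  # breeding mode

    def __post_init__(self) -> None:
        if self.n_pigs < 1:
            raise ValueError("need at least one pig")
        if self.mode not in ("aisle", "breeding"):
            raise ValueError("mode must be 'aisle' or 'breeding'")
        if self.speed_range[0] <= 0:
            raise ValueError("speeds must be positive")
        if self.speed_range[1] > MAX_SPEED_PX:
            raise ValueError(f"speed exceeds the 3 m/s analogue ({MAX_SPEED_PX:.1f} px/frame)")
        if self.mode == "breeding" and self.duration is None:
            raise ValueError("breeding mode needs an explicit duration")


@dataclass(frozen=True)
class PigTruth:
    pig_id: int
    entry_side: str            # left | right | pen
    entry_frame: int
    last_frame: int
    crossed: bool
    turnbacks: int
    body_len: float
    body_h: float
    texture_seed: int


@dataclass
class GroundTruth:
    """Per-frame ground-truth boxes plus per-pig metadata."""

    frames: dict[int, list[tuple[int, Box]]]
    body_frames: dict[int, list[tuple[int, tuple[float, float, float, float]]]]
    pigs: dict[int, PigTruth]
    n_frames: int
    frame_width: float
    frame_height: float

    def tracks(self) -> dict[int, list[Box]]:
        out: dict[int, list[Box]] = {pid: [] for pid in self.pigs}
        for f in sorted(self.frames):
            for pid, box in self.frames[f]:
                out[pid].append(box)
        return {pid: boxes for pid, boxes in out.items() if boxes}

    @property
    def n_pigs(self) -> int:
        return len(self.pigs)


def _visible_box(x: float, cy: float, body_len: float, body_h: float,
                 width: float, height: float) -> Box | None:
    x1 = max(0.0, x - body_len / 2.0)
    x2 = min(width, x + body_len / 2.0)
    y1 = max(0.0, cy - body_h / 2.0)
    y2 = min(height, cy + body_h / 2.0)
    if x2 - x1 < 4.0 or y2 - y1 < 4.0:
        return None
    return Box.from_tlbr(x1, y1, x2, y2)


def _aisle_trajectory(x0: float, direction: int, speed: float, width: float,
                      body_len: float, reversal_xs: list[float], max_frames: int,
                      ) -> tuple[list[float], int]:
    """Per-frame body-center x positions until fully out of frame.

    ``reversal_xs`` are corridor positions at which the velocity flips (in
    encounter order).  Returns positions and the number of reversals taken.
    """
    xs = [x0]
    v = direction * speed
    pending = list(reversal_xs)
    flips = 0
    x = x0
    for _ in range(max_frames):
        x = x + v
        if pending:
            target = pending[0]
            if (v > 0 and x >= target) or (v < 0 and x <= target):
                v = -v
                flips += 1
                pending.pop(0)
        xs.append(x)
        if x < -body_len / 2 - 1 or x > width + body_len / 2 + 1:
            break
    return xs, flips


def generate_scenario(params: SimParams, seed: int) -> GroundTruth:
    """Deterministic ground truth for the given parameters and seed."""
    rng = np.random.default_rng(seed)
    s = params.scale
    width = params.frame_width * s
    height = params.frame_height * s

    pigs: dict[int, PigTruth] = {}
    frames: dict[int, list[tuple[int, Box]]] = {}
    body_frames: dict[int, list[tuple[int, tuple[float, float, float, float]]]] = {}

    max_h = params.body_h_range[1] * s
    n_lanes = max(2, int(height // (1.3 * max_h)))
    lane_centers = [(i + 0.5) * height / n_lanes for i in range(n_lanes)]

    turn_by_pig: dict[int, TurnbackSpec] = {t.pig_index: t for t in params.turnbacks}

    if params.mode == "aisle":
        # disjoint lane bands per entry side so opposite streams never collide
        split = (n_lanes + 1) // 2
        side_lanes = {"left": list(range(split)), "right": list(range(split, n_lanes))}
        next_entry = {"left": 0, "right": 0}
        lane_pos = {"left": 0, "right": 0}
        # per-lane scheduling: a lane reopens only once the previous body has
        # cleared the entry edge, and a follower never outruns its leader
        lane_free: dict[int, int] = {}
        lane_speed: dict[int, float] = {}
        last_frame_seen = 0
        crowd_ids = set()
        for i in range(params.crowding_pairs):
            crowd_ids.add(2 * i + 1)  # pig 2i+1 enters alongside pig 2i

        for idx in range(params.n_pigs):
            pid = idx + 1
            side = "left" if rng.random() < 0.5 else "right"
            body_len = rng.uniform(*params.body_len_range) * s
            body_h = rng.uniform(*params.body_h_range) * s
            speed = rng.uniform(*params.speed_range) * s
            is_crowd = idx in crowd_ids and idx > 0
            if is_crowd:
                # enters alongside the previous pig, one lane over
                prev = pigs[pid - 1]
                side = prev.entry_side
                entry = prev.entry_frame
            else:
                entry = next_entry[side]
            lanes = side_lanes[side]
            lane = lanes[lane_pos[side] % len(lanes)]
            lane_pos[side] += 1
            if lane in lane_free:
                entry = max(entry, lane_free[lane])
                speed = min(speed, lane_speed[lane])
            lane_free[lane] = entry + int(math.ceil(1.5 * body_len / speed)) + 3
            lane_speed[lane] = speed
            if not is_crowd:
                next_entry[side] = max(next_entry[side], entry
                                       + int(rng.integers(*params.entry_gap_range)))
            cy = lane_centers[lane] + rng.uniform(-0.03, 0.03) * height
            cy = min(max(cy, body_h / 2 + 2), height - body_h / 2 - 2)

            direction = 1 if side == "left" else -1
            x0 = -body_len / 2 if side == "left" else width + body_len / 2
            reversal_xs: list[float] = []
            tb = turn_by_pig.get(idx)
            if tb is not None:
                span = width + body_len
                p1 = x0 + direction * tb.at_progress * span
                reversal_xs.append(p1)
                if tb.again_at_progress is not None:
                    reversal_xs.append(x0 + direction * tb.again_at_progress * span)
            xs, flips = _aisle_trajectory(x0, direction, speed, width, body_len,
                                          reversal_xs, max_frames=4000)

            wobble_amp = 0.04 * body_h
            wobble_period = rng.uniform(20, 40)
            wobble_phase = rng.uniform(0, 2 * math.pi)
            texture_seed = int(rng.integers(0, 2**31 - 1))

            last_f = entry
            final_x = xs[-1]
            for k, x in enumerate(xs):
                f = entry + k
                cyk = cy + wobble_amp * math.sin(2 * math.pi * k / wobble_period + wobble_phase)
                box = _visible_box(x, cyk, body_len, body_h, width, height)
                if box is not None:
                    frames.setdefault(f, []).append((pid, box))
                    body_frames.setdefault(f, []).append(
                        (pid, (x - body_len / 2, cyk - body_h / 2, body_len, body_h)))
                    last_f = f
            crossed = ((side == "left" and final_x > width) or
                       (side == "right" and final_x < 0))
            pigs[pid] = PigTruth(pid, side, entry, last_f, crossed, flips,
                                 body_len, body_h, texture_seed)
            last_frame_seen = max(last_frame_seen, last_f)
        n_frames = params.duration if params.duration is not None else last_frame_seen + 5

    else:  # breeding pen: pigs persist for the whole clip
        n_frames = int(params.duration)
        for idx in range(params.n_pigs):
            pid = idx + 1
            body_len = rng.uniform(*params.body_len_range) * s
            body_h = rng.uniform(*params.body_h_range) * s
            lane = idx % n_lanes
            cy = lane_centers[lane]
            cy = min(max(cy, body_h / 2 + 2), height - body_h / 2 - 2)
            margin_x = body_len / 2 + 4
            x = rng.uniform(margin_x, width - margin_x)
            target = rng.uniform(margin_x, width - margin_x)
            speed = rng.uniform(*params.wander_speed_range) * s
            texture_seed = int(rng.integers(0, 2**31 - 1))
            for f in range(n_frames):
                if abs(target - x) < speed:
                    target = rng.uniform(margin_x, width - margin_x)
                x += np.sign(target - x) * speed
                box = _visible_box(x, cy, body_len, body_h, width, height)
                if box is not None:
                    frames.setdefault(f, []).append((pid, box))
                    body_frames.setdefault(f, []).append(
                        (pid, (x - body_len / 2, cy - body_h / 2, body_len, body_h)))
            pigs[pid] = PigTruth(pid, "pen", 0, n_frames - 1, False, 0,
                                 body_len, body_h, texture_seed)

    return GroundTruth(frames=frames, body_frames=body_frames, pigs=pigs,
                       n_frames=n_frames, frame_width=width, frame_height=height)


@dataclass(frozen=True)
class Burst:
    """Pig ``pig_id`` is invisible to the detector for ``length`` frames
    starting at ``start``."""

    pig_id: int
    start: int
    length: int

    def covers(self, frame: int) -> bool:
        return self.start <= frame < self.start + self.length


@dataclass(frozen=True)
class DetectionNoise:
    dropout_p: float = 0.0
    jitter_sigma: float = 0.0     # px, at scenario scale
    fp_rate: float = 0.0          # expected false positives per frame
    bursts: tuple[Burst, ...] = ()
    with_features: bool = False
    feature_dim: int = 64
    feature_noise: float = 0.05
    confidence_floor: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_p <= 1.0):
            raise ValueError("dropout_p must be a probability")
        if self.fp_rate < 0 or self.jitter_sigma < 0:
            raise ValueError("noise magnitudes must be non-negative")


def make_bursts(gt: GroundTruth, count: int, length: int, seed: int,
                region: tuple[float, float] = (0.3, 0.7)) -> tuple[Burst, ...]:
    """Burst dropouts placed along pigs' crossings.

    Pigs are taken in a seed-shuffled cycle; each burst starts at a uniform
    fraction of that pig's on-screen span within ``region``.  The first k
    bursts of the same (gt, seed) are a subset of the first k+1, so burst
    severity is nested across counts.
    """
    rng = np.random.default_rng(seed)
    pids = list(gt.pigs)
    order = [pids[i] for i in rng.permutation(len(pids))]
    bursts = []
    for k in range(count):
        pid = order[k % len(order)]
        p = gt.pigs[pid]
        span = p.last_frame - p.entry_frame
        frac = rng.uniform(*region)
        start = p.entry_frame + int(frac * span)
        bursts.append(Burst(pid, start, length))
    return tuple(bursts)


def _id_feature(scenario_seed: int, pig_id: int, dim: int) -> np.ndarray:
    rng = np.random.default_rng((scenario_seed * 1_000_003 + pig_id) % (2**31 - 1))
    v = rng.normal(size=dim)
    return (v / np.linalg.norm(v)).astype(np.float32)


def oracle_detections(gt: GroundTruth, noise: DetectionNoise | None = None,
                      seed: int = 0) -> list[list[Detection]]:
    """Detections synthesized from ground truth under the noise model.

    Returns one detection list per frame, 0..n_frames-1.  With zero noise
    the detections equal the ground-truth boxes at confidence 1.
    """
    noise = noise or DetectionNoise()
    rng = np.random.default_rng(seed)
    feats = ({pid: _id_feature(seed, pid, noise.feature_dim) for pid in gt.pigs}
             if noise.with_features else {})
    out: list[list[Detection]] = []
    for f in range(gt.n_frames):
        dets: list[Detection] = []
        for pid, box in gt.frames.get(f, []):
            u = float(rng.random())
            jx, jy = rng.normal(0.0, 1.0, size=2)
            if noise.with_features:
                fnoise = rng.normal(0.0, 1.0, size=noise.feature_dim)
            dropped = (u < noise.dropout_p) or any(
                b.pig_id == pid and b.covers(f) for b in noise.bursts)
            if dropped:
                continue
            jxs, jys = jx * noise.jitter_sigma, jy * noise.jitter_sigma
            cx = box.cx + jxs
            cy = box.cy + jys
            conf = max(noise.confidence_floor,
                       min(1.0, 1.0 - math.hypot(jxs, jys) / box.h))
            feat = None
            if noise.with_features:
                v = feats[pid] + noise.feature_noise * fnoise
                feat = (v / np.linalg.norm(v)).astype(np.float32)
            dets.append(Detection(Box(cx, cy, box.gamma, box.h), conf, feat, f))
        n_fp = int(rng.poisson(noise.fp_rate))
        for _ in range(n_fp):
            h = rng.uniform(0.4, 0.9) * gt.frame_height * 0.15
            g = rng.uniform(1.5, 3.5)
            cx = rng.uniform(h * g / 2, gt.frame_width - h * g / 2)
            cy = rng.uniform(h / 2, gt.frame_height - h / 2)
            conf = rng.uniform(0.5, 0.8)
            feat = None
            if noise.with_features:
                v = rng.normal(size=noise.feature_dim)
                feat = (v / np.linalg.norm(v)).astype(np.float32)
            dets.append(Detection(Box(cx, cy, g, h), conf, feat, f))
        out.append(dets)
    return out


def edge_flicker_scenario(seed: int, scale: float = 0.25, cycles: int = 3,
                          visible_len: int = 12, gap_len: int = 40,
                          side: str = "left") -> GroundTruth:
    """One pig lingering and flickering at a frame edge before crossing.

    The animal repeatedly pokes part of its body into view (about a third
    of its length, for ``visible_len`` frames) and withdraws completely
    (for ``gap_len`` frames — longer than the default track max_age, so
    each reappearance births a fresh identity), then finally walks through.
    The scenario that makes naive distinct-id counting overcount and the
    frame-number/area rule count exactly one.
    """
    rng = np.random.default_rng(seed)
    width = FULL_WIDTH * scale
    height = FULL_HEIGHT * scale
    body_len = rng.uniform(500, 630) * scale
    body_h = rng.uniform(170, 215) * scale
    speed = rng.uniform(40, 80) * scale
    cy = height / 2
    frames: dict[int, list[tuple[int, Box]]] = {}
    body_frames: dict[int, list[tuple[int, tuple[float, float, float, float]]]] = {}
    pid = 1
    f = 0
    edge_x = (-body_len / 2) if side == "left" else (width + body_len / 2)
    peek = 0.3 * body_len
    for _ in range(cycles):
        for _ in range(visible_len):
            x = edge_x + (peek if side == "left" else -peek)
            box = _visible_box(x, cy, body_len, body_h, width, height)
            if box is not None:
                frames.setdefault(f, []).append((pid, box))
                body_frames.setdefault(f, []).append(
                    (pid, (x - body_len / 2, cy - body_h / 2, body_len, body_h)))
            f += 1
        f += gap_len
    direction = 1 if side == "left" else -1
    xs, _ = _aisle_trajectory(edge_x, direction, speed, width, body_len, [], 4000)
    entry = f
    last_f = f
    for k, x in enumerate(xs):
        box = _visible_box(x, cy, body_len, body_h, width, height)
        if box is not None:
            frames.setdefault(entry + k, []).append((pid, box))
            body_frames.setdefault(entry + k, []).append(
                (pid, (x - body_len / 2, cy - body_h / 2, body_len, body_h)))
            last_f = entry + k
    pigs = {pid: PigTruth(pid, side, 0, last_f, True, 0, body_len, body_h,
                          int(rng.integers(0, 2**31 - 1)))}
    return GroundTruth(frames=frames, body_frames=body_frames, pigs=pigs,
                       n_frames=last_f + 5, frame_width=width, frame_height=height)


# ------------------------------------------------------------------ renderer

def texture_params(texture_seed: int) -> dict:
    """Deterministic coat appearance for one identity."""
    rng = np.random.default_rng(texture_seed % (2**31 - 1))
    return {
        "base_gray": float(rng.uniform(0.35, 0.85)),
        "tint": rng.uniform(0.85, 1.0, size=3),
        "n_spots": int(rng.integers(0, 10)),
        "spot_xy": rng.uniform(-0.75, 0.75, size=(10, 2)),
        "spot_r": float(rng.uniform(0.08, 0.18)),
        "spot_gray": float(rng.uniform(0.05, 0.3)),
    }


def _draw_pig(canvas: np.ndarray, rect: tuple[float, float, float, float],
              tex: dict, angle: float = 0.0) -> None:
    """Draw a textured ellipse inscribed in ``rect`` onto an RGB canvas."""
    H, W = canvas.shape[:2]
    x0, y0, bw, bh = rect
    cx, cy = x0 + bw / 2, y0 + bh / 2
    xs = np.arange(W) - cx
    ys = np.arange(H) - cy
    X, Y = np.meshgrid(xs, ys)
    ca, sa = math.cos(angle), math.sin(angle)
    Xr = ca * X + sa * Y
    Yr = -sa * X + ca * Y
    a, b = bw / 2 * 0.95, bh / 2 * 0.92
    if a <= 0 or b <= 0:
        return
    inside = (Xr / a) ** 2 + (Yr / b) ** 2 <= 1.0
    color = tex["base_gray"] * tex["tint"]
    canvas[inside] = color
    for i in range(tex["n_spots"]):
        sx, sy = tex["spot_xy"][i]
        r = tex["spot_r"] * min(a, b) * 2
        spot = ((Xr - sx * a) ** 2 + (Yr - sy * b) ** 2 <= r * r) & inside
        canvas[spot] = tex["spot_gray"] * tex["tint"]


def render_crops(n_ids: int, per_id: int, hw: tuple[int, int] = (32, 64),
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Labeled pig crops for embedding training.

    Each identity keeps its coat texture across crops while pose (rotation,
    size, offset) and pixel noise vary.  Returns (crops, labels) with crops
    float32 (N, 3, h, w) in [0, 1].
    """
    h, w = hw
    rng = np.random.default_rng(seed)
    crops = np.empty((n_ids * per_id, 3, h, w), dtype=np.float32)
    labels = np.empty(n_ids * per_id, dtype=np.int64)
    k = 0
    for ident in range(n_ids):
        tex = texture_params(int(rng.integers(0, 2**31 - 1)))
        for _ in range(per_id):
            canvas = rng.normal(0.45, 0.06, size=(h, w, 3)).astype(np.float32)
            scale = rng.uniform(0.85, 1.0)
            bw, bh = w * scale, h * scale
            x0 = (w - bw) / 2 + rng.uniform(-0.05, 0.05) * w
            y0 = (h - bh) / 2 + rng.uniform(-0.05, 0.05) * h
            angle = rng.uniform(-0.25, 0.25)
            _draw_pig(canvas, (x0, y0, bw, bh), tex, angle)
            canvas += rng.normal(0.0, 0.02, size=canvas.shape).astype(np.float32)
            crops[k] = np.clip(canvas, 0.0, 1.0).transpose(2, 0, 1)
            labels[k] = ident
            k += 1
    return crops, labels


def render_frames(gt: GroundTruth, seed: int = 0,
                  frame_range: tuple[int, int] | None = None) -> list[np.ndarray]:
    """Render scenario frames as uint8 RGB images (H, W, 3)."""
    rng = np.random.default_rng(seed)
    H, W = int(round(gt.frame_height)), int(round(gt.frame_width))
    lo, hi = frame_range if frame_range is not None else (0, gt.n_frames)
    frames = []
    for f in range(lo, hi):
        canvas = rng.normal(0.5, 0.05, size=(H, W, 3)).astype(np.float32)
        for pid, rect in gt.body_frames.get(f, []):
            tex = texture_params(gt.pigs[pid].texture_seed)
            _draw_pig(canvas, rect, tex)
        frames.append((np.clip(canvas, 0, 1) * 255).astype(np.uint8))
    return frames
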