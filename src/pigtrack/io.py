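"""File formats and run configuration.

MOT-Challenge delimited files are the interchange format for detections and
tracks: ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z`` with
1-based frame indices in the file and 0-based frames internally (converted
at this boundary).  Detections carry id -1.  YOLO label files (one
``class cx cy w h`` row per box, normalized) are written for detector
evaluation.  ``RunConfig`` round-trips losslessly through YAML and rejects
unknown keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .boxes import Box
from .correction import CountingStats
from .tracker import Detection, TrackerConfig

__all__ = ["MotRow", "read_mot", "write_mot", "detections_from_mot",
           "detections_to_rows", "tracks_to_rows", "write_yolo_labels",
           "RunConfig", "load_config", "save_config", "config_hash",
           "write_audit"]


@dataclass(frozen=True)
class MotRow:
    """One MOT file row with the frame already 0-based."""

    frame: int
    id: int
    box: Box
    conf: float = 1.0


def read_mot(path: str | Path) -> list[MotRow]:
    """Parse a MOT det/gt file; malformed rows raise with their line number."""
    rows: list[MotRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 fields, got {len(parts)}")
            try:
                frame = int(float(parts[0]))
                tid = int(float(parts[1]))
                x, y, w, h = (float(p) for p in parts[2:6])
                conf = float(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if frame < 1:
                raise ValueError(f"{path}:{lineno}: frame indices are 1-based, got {frame}")
            if w <= 0 or h <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive box extent w={w} h={h}")
            rows.append(MotRow(frame - 1, tid, Box.from_tlwh(x, y, w, h), conf))
    return rows


def write_mot(path: str | Path, rows: list[MotRow]) -> None:
    with open(path, "w") as fh:
        for r in sorted(rows, key=lambda r: (r.frame, r.id)):
            x, y, w, h = r.box.tlwh
            fh.write(f"{r.frame + 1},{r.id},{x:.6g},{y:.6g},{w:.6g},{h:.6g},"
                     f"{r.conf:.6g},-1,-1,-1\n")


def detections_from_mot(rows: list[MotRow]) -> list[list[Detection]]:
    """Group MOT detection rows into per-frame lists (0..max frame)."""
    if not rows:
        return []
    n = max(r.frame for r in rows) + 1
    out: list[list[Detection]] = [[] for _ in range(n)]
    for r in rows:
        out[r.frame].append(Detection(r.box, min(max(r.conf, 0.0), 1.0), None, r.frame))
    return out


def detections_to_rows(frames: list[list[Detection]]) -> list[MotRow]:
    return [MotRow(f, -1, d.box, d.confidence)
            for f, dets in enumerate(frames) for d in dets]


def tracks_to_rows(frames: dict[int, list[tuple[int, Box]]]) -> list[MotRow]:
    return [MotRow(f, tid, box) for f, items in frames.items() for tid, box in items]


def write_yolo_labels(path: str | Path, boxes: list[Box],
                      frame_width: float, frame_height: float, cls: int = 0) -> None:
    """One normalized ``class cx cy w h`` row per box."""
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{cls} {b.cx / frame_width:.6f} {b.cy / frame_height:.6f} "
                     f"{b.w / frame_width:.6f} {b.h / frame_height:.6f}\n")


@dataclass
class RunConfig:
    """Everything a run needs, round-trippable through one YAML file."""

    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    stats: CountingStats = field(default_factory=CountingStats)
    frame_width: float = 2688.0
    frame_height: float = 1520.0
    seed: int = 0
    enable_correction: bool = True
    enable_turnback: bool = True
    smooth_window: int = 5
    hysteresis_frac: float = 0.1


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "tracker" in kwargs:
        kwargs["tracker"] = _from_mapping(TrackerConfig, kwargs["tracker"])
    if "stats" in kwargs:
        kwargs["stats"] = _from_mapping(CountingStats, kwargs["stats"])
    return RunConfig(**kwargs)


def save_config(path: str | Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_audit(path: str | Path, audit) -> None:
    """Write the counting audit trail as a tab-separated table."""
    with open(path, "w") as fh:
        fh.write("frame\tid\tevent\tcount\n")
        for ev in audit:
            fh.write(f"{ev.frame}\t{ev.id}\t{ev.event}\t{ev.count}\n")
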