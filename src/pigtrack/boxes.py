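"""Bounding-box geometry.

Boxes follow the tracking convention used throughout the package:
``(cx, cy, gamma, h)`` where ``cx, cy`` is the box center in pixels,
``gamma = w / h`` is the aspect ratio and ``h`` the height in pixels.
Box area in this convention is ``gamma * h**2 = w * h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["Box", "CIOUBreakdown", "iou", "ciou_loss"]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box as (center-x, center-y, aspect w/h, height), pixels."""

    cx: float
    cy: float
    gamma: float
    h: float

    def __post_init__(self) -> None:
        if not (self.h > 0 and self.gamma > 0):
            raise ValueError(f"box requires h > 0 and gamma > 0, got {self}")

    @property
    def w(self) -> float:
        return self.gamma * self.h

    @property
    def area(self) -> float:
        return self.gamma * self.h * self.h

    @property
    def tlwh(self) -> tuple[float, float, float, float]:
        w = self.w
        return (self.cx - w / 2.0, self.cy - self.h / 2.0, w, self.h)

    @property
    def tlbr(self) -> tuple[float, float, float, float]:
        x, y, w, h = self.tlwh
        return (x, y, x + w, y + h)

    @classmethod
    def from_tlwh(cls, x: float, y: float, w: float, h: float) -> "Box":
        if w <= 0 or h <= 0:
            raise ValueError(f"tlwh box requires positive extents, got w={w}, h={h}")
        return cls(x + w / 2.0, y + h / 2.0, w / h, h)

    @classmethod
    def from_tlbr(cls, x1: float, y1: float, x2: float, y2: float) -> "Box":
        return cls.from_tlwh(x1, y1, x2 - x1, y2 - y1)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    ax1, ay1, ax2, ay2 = a.tlbr
    bx1, by1, bx2, by2 = b.tlbr
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


@dataclass(frozen=True)
class CIOUBreakdown:
    """Terms of the complete-IOU loss.

    loss = 1 - iou + rho2 / c2 + alpha * v_aspect, where rho2 is the squared
    center distance, c2 the squared diagonal of the smallest enclosing box,
    v_aspect the normalized squared aspect-ratio difference and alpha its
    influence factor.
    """

    iou: float
    rho2: float
    c2: float
    v_aspect: float
    alpha: float
    loss: float


def ciou_loss(pred: Box, truth: Box) -> CIOUBreakdown:
    """Complete-IOU loss between a predicted and a ground-truth box.

    Combines overlap, normalized center distance and aspect-ratio
    consistency.  Zero exactly when the boxes coincide.  For a perfect
    match the 0/0 influence factor is defined as alpha = 0.
    """
    overlap = iou(pred, truth)
    rho2 = (pred.cx - truth.cx) ** 2 + (pred.cy - truth.cy) ** 2

    px1, py1, px2, py2 = pred.tlbr
    tx1, ty1, tx2, ty2 = truth.tlbr
    cw = max(px2, tx2) - min(px1, tx1)
    ch = max(py2, ty2) - min(py1, ty1)
    c2 = cw * cw + ch * ch

    dt = math.atan(truth.w / truth.h) - math.atan(pred.w / pred.h)
    v = (4.0 / math.pi**2) * dt * dt
    denom = (1.0 - overlap) + v
    alpha = v / denom if denom > 0 else 0.0

    loss = 1.0 - overlap + rho2 / c2 + alpha * v
    return CIOUBreakdown(iou=overlap, rho2=rho2, c2=c2, v_aspect=v, alpha=alpha, loss=loss)
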