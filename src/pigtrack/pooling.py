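"""SoftPool and spatial-pyramid-pooling (SPP) operators.

SoftPool replaces the max in a pooling window by the softmax-weighted mean
of the window's activations: each activation ``a_i`` in a window S receives
weight ``w_i = exp(a_i) / sum_j exp(a_j)`` and the pooled value is
``sum_i w_i * a_i``.  This is a smooth interpolation between average pooling
(flat activations) and max pooling (one dominant activation) that keeps more
of the detail that a hard max discards — which is what makes partially
visible animal body parts survive the detector neck.

The SPP block concatenates the input with SoftPool-pooled copies at several
window sizes ("same" padded, stride 1), so the spatial extent is preserved
and the channel count multiplies by the number of branches.  Two presets are
provided: ``SPP1`` with windows 1/11/13/15 and ``SPP2`` with windows 1/3/5/7.

Padding is masked rather than zero-filled: padded positions are excluded
from the softmax so edge windows are pooled over real activations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["softpool", "softpool2d", "SPPSpec", "SPP1", "SPP2", "spp_block"]


def softpool(activations) -> float:
    """Softmax-weighted average of a pooling region, numerically stable.

    Accepts any non-empty array-like of finite activations (the window's
    shape is irrelevant: pooling is over the flattened region).
    """
    a = np.asarray(activations, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("softpool over an empty region")
    if not np.all(np.isfinite(a)):
        raise ValueError("softpool requires finite activations")
    e = np.exp(a - a.max())
    w = e / e.sum()
    return float(w @ a)


def _pool_windows(x: np.ndarray, window: int, stride: int, kind: str) -> np.ndarray:
    """Pool each (window x window) patch of a (C,H,W) map, 'same'-padded.

    Padded positions carry -inf and are masked out of the pooling sum.
    """
    c, h, w = x.shape
    pad = window // 2
    xp = np.full((c, h + 2 * pad, w + 2 * pad), -np.inf, dtype=float)
    xp[:, pad : pad + h, pad : pad + w] = x
    win = sliding_window_view(xp, (window, window), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C, Ho, Wo, k, k)
    flat = win.reshape(*win.shape[:3], -1)
    if kind == "maxpool":
        return flat.max(axis=-1)
    m = flat.max(axis=-1, keepdims=True)
    e = np.exp(flat - m)  # exp(-inf - m) = 0: padding gets zero weight
    wgt = e / e.sum(axis=-1, keepdims=True)
    safe = np.where(np.isfinite(flat), flat, 0.0)
    return (wgt * safe).sum(axis=-1)


def softpool2d(fmap, window: int, stride: int = 1) -> np.ndarray:
    """Sliding-window SoftPool over a channel-first (C, H, W) feature map.

    With the default stride 1 the output has the same spatial extent as the
    input ("same" padding); a 1x1 window is the identity.
    """
    x = np.asarray(fmap, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("feature map must be (C, H, W) or (H, W)")
    if not np.all(np.isfinite(x)):
        raise ValueError("softpool2d requires finite activations")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > min(x.shape[1], x.shape[2]) + 2 * (window // 2):
        raise ValueError("window larger than the padded map")
    out = _pool_windows(x, window, stride, "softpool")
    return out if np.asarray(fmap).ndim == 3 else out[0]


@dataclass(frozen=True)
class SPPSpec:
    """Spatial-pyramid-pooling block: window sizes and pooling kind.

    Window sizes must be odd so that symmetric "same" padding exists; a
    1-window branch passes the input through unchanged.
    """

    block_sizes: tuple[int, ...] = (1, 3, 5, 7)
    pool_kind: str = "softpool"

    def __post_init__(self) -> None:
        if not self.block_sizes:
            raise ValueError("SPP spec needs at least one block size")
        for b in self.block_sizes:
            if b < 1 or b % 2 == 0:
                raise ValueError(f"SPP block sizes must be odd and >= 1, got {b}")
        if self.pool_kind not in ("softpool", "maxpool"):
            raise ValueError(f"unknown pool kind {self.pool_kind!r}")


#: Coarse pyramid used early in the detector neck (large receptive fields).
SPP1 = SPPSpec((1, 11, 13, 15))
#: Fine pyramid used later in the neck.
SPP2 = SPPSpec((1, 3, 5, 7))


def spp_block(fmap, spec: SPPSpec = SPP2) -> np.ndarray:
    """Concatenate pooled copies of a (C, H, W) map along channels.

    Output channel count is ``C * len(spec.block_sizes)``; spatial extent is
    preserved by stride-1 "same" pooling.
    """
    x = np.asarray(fmap, dtype=float)
    if x.ndim != 3:
        raise ValueError("feature map must be (C, H, W)")
    branches = []
    for b in spec.block_sizes:
        if b == 1:
            branches.append(x)
        else:
            branches.append(_pool_windows(x, b, 1, spec.pool_kind))
    return np.concatenate(branches, axis=0)
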