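"""The detector-side operators: SoftPool, SPP blocks and the CIOU loss.

SoftPool replaces a window's max with its softmax-weighted mean, keeping
detail a hard max discards; the two spatial-pyramid-pooling blocks stack
pooled copies at windows 1/11/13/15 (coarse) and 1/3/5/7 (fine); the
complete-IOU loss scores box regression by overlap, center distance and
aspect consistency at once.
"""

import numpy as np

from pigtrack import SPP1, SPP2, Box, ciou_loss, softpool, softpool2d, spp_block

window = np.array([0.0, np.log(3.0)])
print(f"softpool of [0, ln 3]: {softpool(window):.4f} "
      f"(max would give {window.max():.4f}, mean {window.mean():.4f})")

fmap = np.random.default_rng(0).normal(size=(8, 20, 20))
out1 = spp_block(fmap, SPP1)
out2 = spp_block(fmap, SPP2)
print(f"SPP1 {SPP1.block_sizes}: {fmap.shape} -> {out1.shape}")
print(f"SPP2 {SPP2.block_sizes}: {fmap.shape} -> {out2.shape}")
pooled = softpool2d(fmap, window=3)
print(f"softpool2d keeps extent: {fmap.shape} -> {pooled.shape}; "
      f"window-mean lower bound holds: {bool((pooled >= fmap.mean() - 3).all())}")

pred = Box.from_tlwh(0, 0, 1, 1)
truth = Box.from_tlwh(1, 1, 1, 1)
out = ciou_loss(pred, truth)
print(f"CIOU of corner-touching unit boxes: loss={out.loss:.2f} "
      f"(iou={out.iou}, rho2/c2={out.rho2 / out.c2:.2f}, alpha*v={out.alpha * out.v_aspect:.2f})")
print(f"CIOU of identical boxes: {ciou_loss(pred, pred).loss:.2f}")
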