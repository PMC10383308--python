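"""Pig re-identification embeddings.

A compact residual CNN maps a pig crop to a unit-norm appearance vector so
the same animal can be matched across frames by cosine distance.  The
default layout follows the published architecture: one 3x3 convolution, one
overlapping max pool, nine residual layers (stride-2 downsampling at the
32->64, 64->128, 128->256 and 256->512 channel transitions) and a final
average pool, giving a 512-dimensional embedding.  Crops are wide (width :
height = 2 : 1): pigs filmed from above are long, unlike the upright 1:2
crops used for pedestrian re-identification.

``width_mult`` scales every channel count (and hence the embedding
dimension) for desk-scale training experiments while keeping the layer
sequence and stride pattern intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import nn
from .boxes import Box

__all__ = ["ReIDSpec", "ReIDExtractor", "build_reid", "preprocess_crop",
           "extract_features", "train_reid", "cosine_distance"]

# (channels, stride) of the nine residual layers at width_mult=1.
_RESIDUAL_PLAN = ((32, 1), (64, 2), (64, 1), (64, 1), (128, 2), (128, 1),
                  (256, 2), (256, 1), (512, 2))


@dataclass(frozen=True)
class ReIDSpec:
    """Architecture hyper-parameters of the embedding network.

    ``input_hw`` is (height, width) of the crop fed to the network and must
    be 2:1 wide.  The embedding dimension equals the final residual layer's
    channel count: 512 at ``width_mult=1``.
    """

    input_hw: tuple[int, int] = (64, 128)
    in_channels: int = 3
    width_mult: float = 1.0
    conv1_channels: int = 32
    residual_plan: tuple[tuple[int, int], ...] = _RESIDUAL_PLAN

    def __post_init__(self) -> None:
        h, w = self.input_hw
        if w != 2 * h:
            raise ValueError(f"crop geometry must be 2:1 (w=2h), got {self.input_hw}")
        if h % 32 != 0:
            raise ValueError("crop height must be a multiple of 32 (five stride-2 stages)")
        if not (0 < self.width_mult <= 1):
            raise ValueError("width_mult must be in (0, 1]")

    def _ch(self, c: int) -> int:
        return max(4, int(round(c * self.width_mult)))

    @property
    def embedding_dim(self) -> int:
        return self._ch(self.residual_plan[-1][0])


class ReIDExtractor:
    """The embedding network plus its preprocessing geometry."""

    def __init__(self, spec: ReIDSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = [
            nn.Conv2d(spec.in_channels, spec._ch(spec.conv1_channels), 3, stride=1, rng=rng),
            nn.MaxPool2d(3, 2, 1),
        ]
        cin = spec._ch(spec.conv1_channels)
        for c, s in spec.residual_plan:
            cout = spec._ch(c)
            layers.append(nn.ResidualBlock(cin, cout, stride=s, rng=rng))
            cin = cout
        layers += [nn.BatchNorm2d(cin), nn.ReLU(), nn.GlobalAvgPool()]
        self.net = nn.Sequential(*layers)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def forward_pooled(self, crops: np.ndarray, train: bool) -> np.ndarray:
        """Raw pooled features (N, embedding_dim), pre-normalization."""
        return self.net.forward(np.asarray(crops, dtype=np.float32), train)

    def embed(self, crops: np.ndarray) -> np.ndarray:
        """Unit-norm embeddings, one row per crop; eval mode."""
        crops = np.asarray(crops, dtype=np.float32)
        if crops.ndim == 3:
            crops = crops[None]
        if crops.shape[0] == 0:
            return np.zeros((0, self.spec.embedding_dim), dtype=np.float32)
        feats = self.forward_pooled(crops, train=False)
        norms = np.linalg.norm(feats, axis=1, keepdims=True)
        return feats / np.maximum(norms, 1e-12)


    def _bn_layers(self) -> list[nn.BatchNorm2d]:
        out = []
        for layer in self.net.layers:
            if isinstance(layer, nn.BatchNorm2d):
                out.append(layer)
            elif isinstance(layer, nn.ResidualBlock):
                out.extend([layer.bn1, layer.bn2])
        return out

    def save(self, path) -> None:
        """Serialize weights and running statistics to one .npz file."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        spec = self.spec
        arrays["spec"] = np.array([spec.input_hw[0], spec.input_hw[1],
                                   spec.in_channels, spec.width_mult], dtype=np.float64)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ReIDExtractor":
        data = np.load(path)
        h, w, cin, wm = data["spec"]
        spec = ReIDSpec(input_hw=(int(h), int(w)), in_channels=int(cin), width_mult=float(wm))
        ex = cls(spec, seed=0)
        for i, p in enumerate(ex.params()):
            p.value[...] = data[f"p{i}"]
        for i, bn in enumerate(ex._bn_layers()):
            bn.running_mean[...] = data[f"rm{i}"]
            bn.running_var[...] = data[f"rv{i}"]
        return ex


def build_reid(spec: ReIDSpec | None = None, seed: int = 0) -> ReIDExtractor:
    """Construct a randomly initialized embedding network."""
    return ReIDExtractor(spec or ReIDSpec(), seed)


def _resize_channel(ch: np.ndarray, size_wh: tuple[int, int]) -> np.ndarray:
    img = Image.fromarray(ch.astype(np.float32), mode="F")
    return np.asarray(img.resize(size_wh, Image.BILINEAR), dtype=np.float32)


def preprocess_crop(frame: np.ndarray, box: Box, spec: ReIDSpec | None = None) -> np.ndarray:
    """Crop a box out of a frame and resize to the spec geometry.

    The box is clipped to the frame first; pixel values are returned as
    float32 in [0, 1], channel-first.  Deterministic: the same frame and box
    always yield bit-identical crops.
    """
    spec = spec or ReIDSpec()
    frame = np.asarray(frame)
    fh, fw = frame.shape[:2]
    x1, y1, x2, y2 = box.tlbr
    x1, x2 = max(0, int(np.floor(x1))), min(fw, int(np.ceil(x2)))
    y1, y2 = max(0, int(np.floor(y1))), min(fh, int(np.ceil(y2)))
    if x2 <= x1 or y2 <= y1:
        raise ValueError("box lies fully outside the frame")
    sub = frame[y1:y2, x1:x2]
    if sub.dtype == np.uint8:
        sub = sub.astype(np.float32) / 255.0
    else:
        sub = sub.astype(np.float32)
    if sub.ndim == 2:
        sub = sub[:, :, None]
    h, w = spec.input_hw
    chans = [_resize_channel(sub[:, :, c], (w, h)) for c in range(sub.shape[2])]
    crop = np.stack(chans, axis=0)
    if crop.shape[0] == 1 and spec.in_channels > 1:
        crop = np.repeat(crop, spec.in_channels, axis=0)
    elif crop.shape[0] != spec.in_channels:
        raise ValueError(f"frame has {crop.shape[0]} channels, spec wants {spec.in_channels}")
    return crop


def extract_features(extractor: ReIDExtractor, frame: np.ndarray,
                     boxes: list[Box]) -> np.ndarray:
    """One unit-norm embedding per box, in box order."""
    if not boxes:
        return np.zeros((0, extractor.spec.embedding_dim), dtype=np.float32)
    crops = np.stack([preprocess_crop(frame, b, extractor.spec) for b in boxes])
    return extractor.embed(crops)


def cosine_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1 - cosine similarity between rows of a and rows of b, in [0, 2]."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    an = a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-12)
    bn = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-12)
    return 1.0 - an @ bn.T


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def train_reid(extractor: ReIDExtractor, crops: np.ndarray, labels: np.ndarray,
               epochs: int = 80, lr: float = 0.05, momentum: float = 0.9,
               weight_decay: float = 5e-4, batch_size: int = 32,
               val_fraction: float = 0.2, seed: int = 0,
               ) -> tuple[ReIDExtractor, dict[str, list[float]]]:
    """Train identity classification on top of the embedding network.

    A linear head over the pooled features is trained jointly with the
    backbone using softmax cross-entropy; held-out accuracy (correct /
    total on a stratified 20% split) is recorded every epoch.  The head is
    discarded: the return value is the embedding extractor plus the
    training history ``{"loss": [...], "acc": [...]}``.
    """
    crops = np.asarray(crops, dtype=np.float32)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("re-ID training needs at least 2 identities")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("every identity needs at least 2 crops")

    rng = np.random.default_rng(seed)
    tr, va = _stratified_split(y, val_fraction, rng)
    head = nn.Linear(extractor.spec.embedding_dim, classes.size, rng=rng)
    opt = nn.SGD(extractor.params() + head.params(), lr=lr, momentum=momentum,
                 weight_decay=weight_decay)

    history: dict[str, list[float]] = {"loss": [], "acc": []}
    for epoch in range(epochs):
        order = rng.permutation(tr)
        # cosine learning-rate schedule
        opt.lr = lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(1, epochs)))
        losses = []
        for start in range(0, order.size, batch_size):
            idx = order[start : start + batch_size]
            xb = crops[idx]
            flip = rng.random(idx.size) < 0.5
            if flip.any():
                xb = xb.copy()
                xb[flip] = xb[flip, :, :, ::-1]
            feats = extractor.forward_pooled(xb, train=True)
            logits = head.forward(feats, train=True)
            loss, gl = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            extractor.net.backward(head.backward(gl))
            opt.step()
            losses.append(loss)
        # held-out accuracy, eval mode
        correct = 0
        for start in range(0, va.size, batch_size):
            idx = va[start : start + batch_size]
            logits = head.forward(extractor.forward_pooled(crops[idx], train=False), train=False)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["acc"].append(correct / va.size)
    return extractor, history
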