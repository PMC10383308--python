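"""Minimal CPU neural-network core (forward + backprop) on numpy.

Provides exactly the layers the re-identification embedding network needs:
3x3 convolutions (im2col), batch normalization, ReLU, overlapping max
pooling, pre-activation residual blocks, global average pooling, a linear
classifier head, softmax cross-entropy and SGD with momentum.  Layout is
channel-first ``(N, C, H, W)`` throughout.

Each layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward``; parameters accumulate
gradients in ``Param.grad``.  Gradient correctness is enforced by numerical
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "ResidualBlock",
    "softmax_cross_entropy",
    "SGD",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C*k*k, ho*wo) patch matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo)


class Conv2d(Layer):
    """k x k convolution, He-initialized, optional bias."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(np.float32))
        self.bias = Param(np.zeros(cout, dtype=np.float32)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train):
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, ho, wo)  # (N, C*k*k, L)
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)  # (cout, C*k*k)
        out = np.einsum("oc,ncl->nol", wmat, cols, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        self._cache = (cols, xp.shape, (n, ho, wo))
        return out.reshape(n, -1, ho, wo)

    def backward(self, grad):
        cols, xp_shape, (n, ho, wo) = self._cache
        cout = self.weight.value.shape[0]
        g = grad.reshape(n, cout, ho * wo)
        wmat = self.weight.value.reshape(cout, -1)
        self.weight.grad += np.einsum("nol,ncl->oc", g, cols, optimize=True).reshape(
            self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        dcols = np.einsum("oc,nol->ncl", wmat, g, optimize=True)
        # col2im scatter-add
        k, s, p = self.k, self.stride, self.pad
        _, c, hp, wp = xp_shape
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return g * inv[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        gxs = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        gsum = g.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return inv[None, :, None, None] * (g - gsum / m - xhat * gxs / m)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """Overlapping max pool (default 3x3 / stride 2, 'same'-style pad 1)."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.full((n, c, h + 2 * p, w + 2 * p), -np.inf, dtype=x.dtype)
        xp[:, :, p : p + h, p : p + w] = x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        out = np.full((n, c, ho, wo), -np.inf, dtype=x.dtype)
        argw = np.zeros((n, c, ho, wo), dtype=np.int8)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            patch = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
            better = patch > out
            out = np.where(better, patch, out)
            argw = np.where(better, np.int8(idx), argw)
        self._cache = (argw, xp.shape, (ho, wo), x.shape)
        return out

    def backward(self, grad):
        argw, xp_shape, (ho, wo), x_shape = self._cache
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            sel = grad * (argw == idx)
            dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += sel
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, p : p + h, p : p + w]


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, scale, size=(cout, cin)).astype(np.float32))
        self.bias = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class ResidualBlock(Layer):
    """Pre-activation residual block; projection shortcut on stride 2 or
    channel change."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.bn1 = BatchNorm2d(cin)
        self.relu1 = ReLU()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, rng=rng)
        self.proj = (Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
                     if (stride != 1 or cin != cout) else None)

    def params(self):
        ps = (self.bn1.params() + self.conv1.params() + self.bn2.params()
              + self.conv2.params())
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train):
        pre = self.relu1.forward(self.bn1.forward(x, train), train)
        out = self.conv1.forward(pre, train)
        out = self.conv2.forward(self.relu2.forward(self.bn2.forward(out, train), train), train)
        short = x if self.proj is None else self.proj.forward(pre, train)
        self._proj_from_pre = self.proj is not None
        return out + short

    def backward(self, grad):
        g = self.conv2.backward(grad)
        g = self.bn2.backward(self.relu2.backward(g))
        g = self.conv1.backward(g)
        if self.proj is not None:
            g = g + self.proj.backward(grad)
            return self.bn1.backward(self.relu1.backward(g))
        return self.bn1.backward(self.relu1.backward(g)) + grad


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v -= self.lr * g
            p.value += v
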