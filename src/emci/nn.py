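"""Minimal deterministic CPU neural-network engine (numpy, NCHW layout).

Implements exactly what the classifier needs: 2-D convolution (im2col),
batch normalization, ReLU, max pooling, global average pooling, dense layers,
residual bottleneck blocks, softmax cross-entropy, and SGD with momentum plus
L2 weight decay. All parameter initialization draws from a caller-supplied
``numpy.random.Generator``, so training is bit-reproducible on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Bottleneck",
    "MultiHeadNet",
    "softmax",
    "softmax_xent",
    "SGDMomentum",
    "build_small_cnn",
    "build_resnet",
]


class Layer:
    """Base layer: forward/backward with per-layer parameter and grad lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    #: parameters exempt from weight decay (batchnorm scale/shift, biases)
    def decay_mask(self) -> list[bool]:
        return [True] * len(self.params)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x.shape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
    return cols.reshape(N, C * kh * kw, Ho * Wo), (Ho, Wo)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x_shape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    dcols = dcols.reshape(N, C, kh, kw, Ho, Wo)
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2D(Layer):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))  # He init
        b = np.zeros(cout)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def decay_mask(self) -> list[bool]:
        return [True, False]

    def forward(self, x, train):
        self._xshape = x.shape
        cols, (Ho, Wo) = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._cols = cols
        w, b = self.params
        out = np.einsum("of,nfp->nop", w, cols) + b[None, :, None]
        return out.reshape(x.shape[0], self.cout, Ho, Wo)

    def backward(self, dout):
        N = dout.shape[0]
        dflat = dout.reshape(N, self.cout, -1)
        w, _ = self.params
        self.grads[0][...] = np.einsum("nop,nfp->of", dflat, self._cols)
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", w, dflat)
        return _col2im(dcols, self._xshape, self.k, self.k, self.stride, self.pad)


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = [np.ones(c), np.zeros(c)]  # gamma, beta
        self.grads = [np.zeros(c), np.zeros(c)]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def decay_mask(self) -> list[bool]:
        return [False, False]

    def forward(self, x, train):
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return gamma[None, :, None, None] * self._xhat + beta[None, :, None, None]

    def backward(self, dout):
        gamma, _ = self.params
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads[0][...] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std[None, :, None, None]
        # mean over (N, H, W) already folded in via keepdims means (n elements)
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(Layer):
    def __init__(self, k: int = 2, stride: int | None = None):
        super().__init__()
        self.k = k
        self.stride = stride or k

    def forward(self, x, train):
        self._xshape = x.shape
        N, C, H, W = x.shape
        k, s = self.k, self.stride
        # pad on the bottom/right so every input pixel is covered
        Ho = max(1, -(-(H - k) // s) + 1) if H >= k else 1
        Wo = max(1, -(-(W - k) // s) + 1) if W >= k else 1
        pad_h = max(0, (Ho - 1) * s + k - H)
        pad_w = max(0, (Wo - 1) * s + k - W)
        xp = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)), constant_values=-np.inf)
        self._pads = (pad_h, pad_w)
        cols = np.empty((N, C, k * k, Ho, Wo), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i * k + j] = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
        self._argmax = cols.argmax(axis=2)
        self._outshape = (N, C, Ho, Wo)
        return cols.max(axis=2)

    def backward(self, dout):
        N, C, H, W = self._xshape
        k, s = self.k, self.stride
        _, _, Ho, Wo = self._outshape
        pad_h, pad_w = self._pads
        dxp = np.zeros((N, C, H + pad_h, W + pad_w), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                sel = self._argmax == (i * k + j)
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dout * sel
        return dxp[:, :, :H, :W]


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._xshape
        return np.broadcast_to(dout[:, :, None, None], self._xshape) / (H * W)


class Dense(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fin), size=(fin, fout))
        b = np.zeros(fout)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def decay_mask(self) -> list[bool]:
        return [True, False]

    def forward(self, x, train):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def walk(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, Bottleneck)):
                yield from layer.walk()
            else:
                yield layer


class Bottleneck(Layer):
    """1x1 -> 3x3 -> 1x1 residual unit with BN after each conv and a final ReLU.

    A 1x1 projection shortcut is inserted when the channel count or stride
    changes; otherwise the shortcut is the identity.
    """

    def __init__(self, cin: int, mid: int, cout: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.branch = Sequential([
            Conv2D(cin, mid, 1, rng=rng), BatchNorm2D(mid), ReLU(),
            Conv2D(mid, mid, 3, stride=stride, rng=rng), BatchNorm2D(mid), ReLU(),
            Conv2D(mid, cout, 1, rng=rng), BatchNorm2D(cout),
        ])
        if stride != 1 or cin != cout:
            self.shortcut: Sequential | None = Sequential(
                [Conv2D(cin, cout, 1, stride=stride, pad=0, rng=rng), BatchNorm2D(cout)]
            )
        else:
            self.shortcut = None

    def forward(self, x, train):
        y = self.branch.forward(x, train)
        s = self.shortcut.forward(x, train) if self.shortcut is not None else x
        self._mask = (y + s) > 0
        return (y + s) * self._mask

    def backward(self, dout):
        d = dout * self._mask
        dx = self.branch.backward(d)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(d)
        else:
            dx = dx + d
        return dx

    def walk(self):
        yield from self.branch.walk()
        if self.shortcut is not None:
            yield from self.shortcut.walk()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient wrt logits; y holds class indices."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class MultiHeadNet:
    """Shared trunk ending in a feature vector, with one dense softmax head per label."""

    def __init__(self, trunk: Sequential, heads: list[Dense]):
        self.trunk = trunk
        self.heads = heads

    def forward(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        feats = self.trunk.forward(x, train)
        return [h.forward(feats, train) for h in self.heads]

    def backward(self, dlogits: list[np.ndarray]) -> None:
        dfeat = sum(h.backward(d) for h, d in zip(self.heads, dlogits))
        self.trunk.backward(dfeat)

    def predict_proba(self, x: np.ndarray) -> list[np.ndarray]:
        return [softmax(l) for l in self.forward(x, train=False)]

    def layers(self):
        yield from self.trunk.walk()
        yield from self.heads

    def state(self) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        for layer in self.layers():
            arrays.extend(layer.params)
            if isinstance(layer, BatchNorm2D):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def set_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.layers():
            for p in layer.params:
                p[...] = next(it)
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


class SGDMomentum:
    """Classic SGD with momentum; L2 weight decay added to the gradient."""

    def __init__(self, net: MultiHeadNet, lr: float, momentum: float, weight_decay: float):
        self.net = net
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [
            [np.zeros_like(p) for p in layer.params] for layer in net.layers()
        ]

    def step(self) -> None:
        for layer, vels in zip(self.net.layers(), self._vel):
            for p, g, v, decay in zip(layer.params, layer.grads, vels, layer.decay_mask()):
                eff = g + self.weight_decay * p if decay else g
                v *= self.momentum
                v -= self.lr * eff
                p += v


def build_small_cnn(n_classes: list[int], in_channels: int = 3,
                    rng: np.random.Generator | None = None) -> MultiHeadNet:
    """Two conv-BN-ReLU blocks with pooling, GAP and dense softmax head(s)."""
    rng = rng or np.random.default_rng(0)
    trunk = Sequential([
        Conv2D(in_channels, 16, 3, rng=rng), BatchNorm2D(16), ReLU(),
        MaxPool2D(2),
        Conv2D(16, 32, 3, rng=rng), BatchNorm2D(32), ReLU(),
        GlobalAvgPool(),
    ])
    heads = [Dense(32, q, rng=rng) for q in n_classes]
    return MultiHeadNet(trunk, heads)


def build_resnet(n_classes: list[int], in_channels: int = 3, width: int = 16,
                 rng: np.random.Generator | None = None) -> MultiHeadNet:
    """ResNet-50 topology: 7x7/2 stem, 3x3/2 max-pool, bottleneck groups of
    3/4/6/3 units, global average pooling, dense softmax head(s).

    ``width`` scales channel counts (the canonical network uses width=64);
    the reduced default keeps CPU training tractable.
    """
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = [
        Conv2D(in_channels, width, 7, stride=2, pad=3, rng=rng),
        BatchNorm2D(width), ReLU(),
        MaxPool2D(3, stride=2),
    ]
    cin = width
    for gi, n_units in enumerate([3, 4, 6, 3]):
        mid = width * (2 ** gi)
        cout = mid * 4
        for ui in range(n_units):
            stride = 2 if (ui == 0 and gi > 0) else 1
            layers.append(Bottleneck(cin, mid, cout, stride, rng))
            cin = cout
    layers.append(GlobalAvgPool())
    trunk = Sequential(layers)
    heads = [Dense(cin, q, rng=rng) for q in n_classes]
    return MultiHeadNet(trunk, heads)
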