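"""A small CPU neural-network engine on numpy.

Implements exactly the pieces the package's models need — 2-D convolution
(stride 1, "same" padding via im2col), ReLU, batch normalization, 2x2 max
pooling, global average pooling, a linear head, residual blocks, softmax
cross-entropy and plain SGD — with analytic backprop throughout.  Layer
activations and their gradients are exposed after each forward/backward pass,
which is what class-activation mapping needs.

Arrays are NCHW ``float64``.  All weight initialisation draws from an
explicit ``numpy.random.Generator``, so a fixed seed gives bit-identical
training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv2d", "ReLU", "BatchNorm2d", "MaxPool2d",
    "GlobalAvgPool", "Linear", "Residual", "Sequential", "SGD",
    "softmax", "softmax_cross_entropy",
    "build_small_cnn", "build_plain_cnn", "build_resnet_small", "build_pixel_net",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list:
        return []


class Conv2d(Layer):
    """k x k convolution, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))   # He init
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out))
        self._cols = None
        self._xshape = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        out = cols @ self.w.value.T + self.b.value
        self._cols, self._xshape = cols, (n, c, h, w)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gout):
        n, c, h, w = self._xshape
        g2 = gout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.w.grad += g2.T @ self._cols
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.value).reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, gout):
        return gout * self._m


class BatchNorm2d(Layer):
    """Per-channel normalization over (N, H, W); batch statistics while
    training, exponential running averages at eval.

    With mini-batch size 1 the layer effectively performs instance
    normalization, and the running averages no longer describe what the
    weights were trained against; setting ``use_batch_stats_at_eval`` keeps
    per-sample statistics at inference (deterministic, since they depend only
    on the input)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.use_batch_stats_at_eval = False

    def forward(self, x, train=True):
        if train or self.use_batch_stats_at_eval:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if train:
                self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
                self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        m = mean[None, :, None, None]
        v = var[None, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + self.eps)
        self._istd = 1.0 / np.sqrt(v + self.eps)
        self._train = train or self.use_batch_stats_at_eval  # batch stats depend on x
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, gout):
        g = self.gamma.value[None, :, None, None]
        self.gamma.grad += (gout * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        gxhat = gout * g
        if not self._train:
            return gxhat * self._istd
        n = gout.shape[0] * gout.shape[2] * gout.shape[3]
        return (
            self._istd
            / n
            * (n * gxhat - gxhat.sum(axis=(0, 2, 3), keepdims=True) - self._xhat * (gxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True))
        )

    def params(self):
        return [self.gamma, self.beta]


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (odd trailing row/col dropped)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : h2 * 2, : w2 * 2]
        r = xc.reshape(n, c, h2, 2, w2, 2)
        out = r.max(axis=(3, 5))
        self._mask = r == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, gout):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        g = self._mask * gout[:, :, :, None, :, None]
        # split ties evenly so gradients stay well-defined
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        g = g / counts
        dx = np.zeros((n, c, h, w))
        dx[:, :, : h2 * 2, : w2 * 2] = g.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / f_in), size=(f_out, f_in)))
        self.b = Param(np.zeros(f_out))

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gout):
        self.w.grad += gout.T @ self._x
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value

    def params(self):
        return [self.w, self.b]


class Residual(Layer):
    """Two conv+BN stages with an identity skip, ReLU after the sum."""

    def __init__(self, c: int, rng: np.random.Generator | None = None):
        self.body = [Conv2d(c, c, 3, rng), BatchNorm2d(c), ReLU(), Conv2d(c, c, 3, rng), BatchNorm2d(c)]
        self.out_relu = ReLU()

    def forward(self, x, train=True):
        y = x
        for layer in self.body:
            y = layer.forward(y, train)
        return self.out_relu.forward(y + x, train)

    def backward(self, gout):
        g = self.out_relu.backward(gout)
        gy = g
        for layer in reversed(self.body):
            gy = layer.backward(gy)
        return gy + g

    def params(self):
        return [p for layer in self.body for p in layer.params()]


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers
        self.activations: list = []   # output of each layer from the last forward

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self.activations = []
        for layer in self.layers:
            x = layer.forward(x, train)
            self.activations.append(x)
        return x

    def backward(self, gout: np.ndarray, upto: int = 0) -> np.ndarray:
        """Backprop from the top; returns the gradient w.r.t. the *input* of
        layer index ``upto`` (equivalently: the output of layer ``upto - 1``)."""
        for layer in reversed(self.layers[upto:]):
            gout = layer.backward(gout)
        return gout

    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params()]


class SGD:
    def __init__(self, params: list, lr: float):
        self.params = params
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            p.value -= self.lr * p.grad


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over rows; returns (loss, dloss/dlogits)."""
    p = softmax(logits, axis=1)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, g / n


# ---------------------------------------------------------------------------
# Model builders


def build_small_cnn(n_classes: int, in_channels: int = 3, width: int = 8, rng: np.random.Generator | None = None) -> Sequential:
    """CPU-friendly classifier: three conv stages with pooling, GAP, linear head."""
    rng = rng or np.random.default_rng(0)
    return Sequential([
        Conv2d(in_channels, width, 3, rng), ReLU(), MaxPool2d(),
        Conv2d(width, 2 * width, 3, rng), BatchNorm2d(2 * width), ReLU(), MaxPool2d(),
        Conv2d(2 * width, 4 * width, 3, rng), BatchNorm2d(4 * width), ReLU(),
        GlobalAvgPool(), Linear(4 * width, n_classes, rng),
    ])


def build_plain_cnn(n_classes: int, in_channels: int = 3, width: int = 8, rng: np.random.Generator | None = None) -> Sequential:
    """Normalization-free variant of the small classifier.

    Without batch normalization no global image statistic is injected into
    local activations, so class evidence stays spatially local — the
    preferred backbone when activation maps are to be read spatially
    (hotspot tracing)."""
    rng = rng or np.random.default_rng(0)
    return Sequential([
        Conv2d(in_channels, width, 3, rng), ReLU(), MaxPool2d(),
        Conv2d(width, 2 * width, 3, rng), ReLU(), MaxPool2d(),
        Conv2d(2 * width, 4 * width, 3, rng), ReLU(),
        GlobalAvgPool(), Linear(4 * width, n_classes, rng),
    ])


def build_resnet_small(n_classes: int, in_channels: int = 3, width: int = 16, rng: np.random.Generator | None = None) -> Sequential:
    """Residual variant of the classifier (deeper; no pretrained weights)."""
    rng = rng or np.random.default_rng(0)
    return Sequential([
        Conv2d(in_channels, width, 3, rng), BatchNorm2d(width), ReLU(), MaxPool2d(),
        Residual(width, rng), MaxPool2d(),
        Residual(width, rng),
        GlobalAvgPool(), Linear(width, n_classes, rng),
    ])


def build_pixel_net(n_channels: int, n_blocks: int = 3, in_channels: int = 3, rng: np.random.Generator | None = None) -> Sequential:
    """Per-pixel labeling network: conv/ReLU/batch-norm blocks followed by a
    1x1 conv + (external) softmax — the iterative unsupervised segmenter's model."""
    rng = rng or np.random.default_rng(0)
    layers: list = []
    c = in_channels
    for _ in range(n_blocks):
        layers += [Conv2d(c, n_channels, 3, rng), ReLU(), BatchNorm2d(n_channels)]
        c = n_channels
    layers += [Conv2d(n_channels, n_channels, 1, rng)]
    return Sequential(layers)
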