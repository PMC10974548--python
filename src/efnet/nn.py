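"""Minimal NumPy neural-network engine.

Implements exactly the layer set the two-branch classifier needs — 2-D
convolution (valid or same padding, stride 1), max pooling, batch
normalization, dropout, dense layers, ReLU — with manual backpropagation and
an Adam optimizer.  Data layout is channels-last: ``(N, H, W, C)`` for
feature maps, ``(N, F)`` after flattening.

Layers are stateful between ``forward`` and ``backward`` (they cache what
the gradient needs); evaluation-mode forward passes are pure functions of
(parameters, input).  Gradient correctness is pinned by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ShapeError(ValueError):
    """A layer cannot be applied to its input shape (kernel/pool too large)."""


class Layer:
    """Base layer: parameter dicts are empty unless overridden."""

    name = "layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def out_shape(self, in_shape):
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def reg_loss(self) -> float:
        return 0.0


def _corr2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of NHWC input with (kh, kw, ci, co) kernel."""
    kh, kw, ci, co = w.shape
    cols = sliding_window_view(x, (kh, kw), axis=(1, 2))       # (N,H',W',C,kh,kw)
    cols = cols.transpose(0, 1, 2, 4, 5, 3)                    # (N,H',W',kh,kw,C)
    n, ho, wo = cols.shape[:3]
    out = cols.reshape(n * ho * wo, kh * kw * ci) @ w.reshape(kh * kw * ci, co)
    return out.reshape(n, ho, wo, co), cols


class Conv2D(Layer):
    """2-D convolution, stride 1; He-initialized; bias included."""

    def __init__(self, kernel, in_ch, filters, padding="valid", rng=None, name="conv"):
        super().__init__()
        self.kh, self.kw = kernel
        self.cin, self.cout = in_ch, filters
        if padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        self.padding = padding
        self.name = name
        rng = rng or np.random.default_rng()
        fan_in = self.kh * self.kw * in_ch
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(self.kh, self.kw, in_ch, filters)),
            "b": np.zeros(filters),
        }

    def _pads(self):
        if self.padding == "valid":
            return (0, 0), (0, 0)
        ph, pw = self.kh - 1, self.kw - 1
        return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if c != self.cin:
            raise ShapeError(f"{self.name}: expected {self.cin} channels, got {c}")
        (pt, pb), (pl, pr) = self._pads()
        ho = h + pt + pb - self.kh + 1
        wo = w + pl + pr - self.kw + 1
        if ho < 1 or wo < 1:
            raise ShapeError(
                f"{self.name}: kernel ({self.kh}x{self.kw}) larger than input ({h}x{w})"
            )
        return (ho, wo, self.cout)

    def forward(self, x, train=False, rng=None):
        self.out_shape(x.shape[1:])
        (pt, pb), (pl, pr) = self._pads()
        if pt or pb or pl or pr:
            x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        self._xpad_shape = x.shape
        y, cols = _corr2d(x, self.params["W"])
        self._cols = cols
        return y + self.params["b"]

    def backward(self, dy):
        kh, kw, ci, co = self.params["W"].shape
        n, ho, wo = dy.shape[:3]
        cols2 = self._cols.reshape(n * ho * wo, kh * kw * ci)
        self.grads["W"] = (cols2.T @ dy.reshape(-1, co)).reshape(kh, kw, ci, co)
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        # input gradient: full correlation of dy with the rotated kernel
        w_rot = self.params["W"][::-1, ::-1].transpose(0, 1, 3, 2)  # (kh,kw,co,ci)
        dy_pad = np.pad(dy, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0)))
        dx_pad, _ = _corr2d(dy_pad, w_rot)
        (pt, pb), (pl, pr) = self._pads()
        h = self._xpad_shape[1] - pt - pb
        w = self._xpad_shape[2] - pl - pr
        return dx_pad[:, pt:pt + h, pl:pl + w, :]


class MaxPool2D(Layer):
    """Max pooling with stride equal to pool size; excess rows/cols dropped."""

    def __init__(self, pool, name="pool"):
        super().__init__()
        self.ph, self.pw = pool
        self.name = name

    def out_shape(self, in_shape):
        h, w, c = in_shape
        ho, wo = h // self.ph, w // self.pw
        if ho < 1 or wo < 1:
            raise ShapeError(
                f"{self.name}: pool ({self.ph}x{self.pw}) larger than input ({h}x{w})"
            )
        return (ho, wo, c)

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        ho, wo, _ = self.out_shape((h, w, c))
        self._in_shape = x.shape
        xc = x[:, :ho * self.ph, :wo * self.pw, :]
        blocks = xc.reshape(n, ho, self.ph, wo, self.pw, c)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, self.ph * self.pw)
        self._argmax = blocks.argmax(axis=-1)
        return blocks.max(axis=-1)

    def backward(self, dy):
        n, h, w, c = self._in_shape
        ho, wo = h // self.ph, w // self.pw
        flat = np.zeros((n, ho, wo, c, self.ph * self.pw), dtype=dy.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        blocks = flat.reshape(n, ho, wo, c, self.ph, self.pw).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        dx[:, :ho * self.ph, :wo * self.pw, :] = blocks.reshape(
            n, ho * self.ph, wo * self.pw, c
        )
        return dx


class BatchNorm(Layer):
    """Per-channel (last axis) batch normalization.

    Training passes use batch statistics and update exponential running
    statistics (Keras-style momentum); evaluation passes use the running
    statistics, making them deterministic.
    """

    def __init__(self, channels, momentum=0.99, eps=1e-3, name="bn"):
        super().__init__()
        self.name = name
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean) / self._std
            self._m = int(np.prod([x.shape[a] for a in axes]))
            self._train_cache = True
            return self.params["gamma"] * self._xhat + self.params["beta"]
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        self._xhat = xhat
        self._train_cache = False
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        if not self._train_cache:
            return dy * g / np.sqrt(self.running_var + self.eps)
        m = self._m
        dxhat = dy * g
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate, name="dropout"):
        super().__init__()
        self.rate = rate
        self.name = name

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng()
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    name = "flatten"

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer with optional L2 penalty on the weights."""

    def __init__(self, n_in, n_out, l2=0.0, rng=None, name="dense"):
        super().__init__()
        self.name = name
        self.l2 = l2
        rng = rng or np.random.default_rng()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def out_shape(self, in_shape):
        (f,) = in_shape
        if f != self.params["W"].shape[0]:
            raise ShapeError(
                f"{self.name}: expected {self.params['W'].shape[0]} features, got {f}"
            )
        return (self.params["W"].shape[1],)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        if self.l2:
            self.grads["W"] = self.grads["W"] + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T

    def reg_loss(self) -> float:
        return float(self.l2 * np.sum(self.params["W"] ** 2)) if self.l2 else 0.0


class ReLU(Layer):
    name = "relu"

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sequential:
    """Ordered layer list with shape tracing."""

    def __init__(self, layers, in_shape):
        self.layers = list(layers)
        self.shapes = [tuple(in_shape)]
        for layer in self.layers:
            self.shapes.append(tuple(layer.out_shape(self.shapes[-1])))

    @property
    def out_shape(self):
        return self.shapes[-1]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def reg_loss(self) -> float:
        return sum(layer.reg_loss() for layer in self.layers)

    def named_params(self, prefix=""):
        for i, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                yield f"{prefix}{i}.{layer.name}.{key}", layer, key, val


class Adam:
    """Adam with a mutable learning rate (for reduce-on-plateau schedules)."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, param_triples):
        """Update parameters in place.

        ``param_triples`` yields (layer, key, value); gradients are read from
        ``layer.grads[key]``.
        """
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for ident, (layer, key) in enumerate(param_triples):
            g = layer.grads[key]
            m = self._m.setdefault(ident, np.zeros_like(g))
            v = self._v.setdefault(ident, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            layer.params[key] -= self.lr * corr * m / (np.sqrt(v) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))
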