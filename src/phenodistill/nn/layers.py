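"""Layer primitives with explicit forward/backward passes.

Conventions: activations are float32 numpy arrays in channels-last (NHWC)
layout, which keeps convolution patch extraction contiguous and therefore
fast on the CPU; each layer caches what its backward pass needs during
``forward`` and handles one forward-backward pair at a time.  Initialisation
draws from a ``numpy.random.Generator`` supplied by the model builder, so two
builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: parameter registry plus train/eval mode flag."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self.training = True

    def add_param(self, name: str, value: np.ndarray) -> Parameter:
        p = Parameter(value)
        self._params[name] = p
        return p

    def parameters(self) -> list[Parameter]:
        return list(self._params.values())

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        return [(prefix + name, p) for name, p in self._params.items()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self):
        self.training = True

    def eval(self):
        self.training = False

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """k x k convolution with 'same'-style zero padding, He-initialised.

    Computed as a sum over the k*k kernel offsets of strided-slice matmuls,
    which on NHWC data needs only cheap contiguous copies.  The weight is
    stored as (k, k, C_in, C_out).
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out))
        self.w = self.add_param("weight", w)
        self.b = self.add_param("bias", np.zeros(c_out)) if bias else None
        self._cache = None

    def _out_hw(self, h, w):
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        b, h, w, _ = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            xp = np.zeros((b, h + 2 * p, w + 2 * p, self.c_in), dtype=DTYPE)
            xp[:, p:p + h, p:p + w, :] = x
        else:
            xp = x
        oh, ow = self._out_hw(h, w)
        y = np.zeros((b * oh * ow, self.c_out), dtype=DTYPE)
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + s * oh:s, j:j + s * ow:s, :].reshape(-1, self.c_in)
                y += patch @ wv[i, j]
        if self.b is not None:
            y += self.b.value
        self._cache = (xp, x.shape, (oh, ow))
        return y.reshape(b, oh, ow, self.c_out)

    def backward(self, grad):
        xp, x_shape, (oh, ow) = self._cache
        b, h, w, _ = x_shape
        k, s, p = self.k, self.stride, self.pad
        g = np.ascontiguousarray(grad, dtype=DTYPE).reshape(-1, self.c_out)
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        dxp = np.zeros_like(xp)
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + s * oh:s, j:j + s * ow:s, :].reshape(-1, self.c_in)
                self.w.grad[i, j] += patch.T @ g
                dxp[:, i:i + s * oh:s, j:j + s * ow:s, :] += \
                    (g @ wv[i, j].T).reshape(b, oh, ow, self.c_in)
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(c))
        self.beta = self.add_param("beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, shape = self._cache
        b, h, w, c = shape
        m = b * h * w
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.value
        if not self.training:
            return g * inv
        gs = g.sum(axis=(0, 1, 2), keepdims=True)
        gxs = (g * xhat).sum(axis=(0, 1, 2), keepdims=True)
        return (inv / m) * (m * g - gs - xhat * gxs)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Module):
    """k x k max pooling; backward routes gradients to the argmax."""

    def __init__(self, k: int = 2, stride: int | None = None, pad: int = 0):
        super().__init__()
        self.k, self.stride, self.pad = k, stride or k, pad
        self._cache = None

    def forward(self, x):
        b, h, w, c = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)),
                    constant_values=-np.inf) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (B, OH, OW, C, k, k)
        oh, ow = win.shape[1], win.shape[2]
        win = win.reshape(b, oh * ow, c, k * k)
        arg = win.argmax(axis=-1)  # (B, OH*OW, C)
        self._cache = (x.shape, arg, (oh, ow))
        return np.take_along_axis(win, arg[..., None], axis=-1)[..., 0].reshape(
            b, oh, ow, c)

    def backward(self, grad):
        x_shape, arg, (oh, ow) = self._cache
        b, h, w, c = x_shape
        k, s, p = self.k, self.stride, self.pad
        hp, wp = h + 2 * p, w + 2 * p
        dx = np.zeros((b, hp * wp, c), dtype=grad.dtype)
        # window top-left corners in the padded image
        oy, ox = np.meshgrid(np.arange(oh) * s, np.arange(ow) * s, indexing="ij")
        corner = (oy * wp + ox).ravel()  # (OH*OW,)
        pos = corner[None, :, None] + (arg // k) * wp + (arg % k)  # (B, OH*OW, C)
        np.add.at(dx, (np.arange(b)[:, None, None], pos,
                       np.arange(c)[None, None, :]), grad.reshape(b, -1, c))
        dx = dx.reshape(b, hp, wp, c)
        if p:
            dx = dx[:, p:hp - p, p:wp - p, :]
        return dx


class GlobalAvgPool(Module):
    """(B, H, W, C) -> (B, C) spatial mean."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        b, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).astype(grad.dtype)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Needs an rng while training."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._mask = None

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training forward")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Module):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.w = self.add_param("weight", w)
        self.b = self.add_param("bias", np.zeros(d_out))
        self._x = None

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=DTYPE)
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def named_parameters(self, prefix: str = ""):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend(layer.named_parameters(f"{prefix}{i}."))
        return out

    def train(self):
        self.training = True
        for layer in self.layers:
            layer.train()

    def eval(self):
        self.training = False
        for layer in self.layers:
            layer.eval()


class LSTM(Module):
    """Single-layer LSTM over (B, T, D) sequences, returning all hidden states.

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1 so early training does not wash out the
    temporal memory.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.d_in, self.d_hidden = d_in, d_hidden
        s_x = np.sqrt(1.0 / d_in)
        s_h = np.sqrt(1.0 / d_hidden)
        self.wx = self.add_param("wx", rng.normal(0, s_x, size=(d_in, 4 * d_hidden)))
        self.wh = self.add_param("wh", rng.normal(0, s_h, size=(d_hidden, 4 * d_hidden)))
        b = np.zeros(4 * d_hidden)
        b[d_hidden:2 * d_hidden] = 1.0
        self.b = self.add_param("bias", b)
        self._cache = None

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        bsz, T, _ = x.shape
        H = self.d_hidden
        h = np.zeros((bsz, H), dtype=DTYPE)
        c = np.zeros((bsz, H), dtype=DTYPE)
        hs = np.zeros((bsz, T, H), dtype=DTYPE)
        cache = []
        for t in range(T):
            gates = x[:, t] @ self.wx.value + h @ self.wh.value + self.b.value
            i = self._sigmoid(gates[:, :H])
            f = self._sigmoid(gates[:, H:2 * H])
            g = np.tanh(gates[:, 2 * H:3 * H])
            o = self._sigmoid(gates[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tc))
        self._cache = (x, hs, cache)
        return hs

    def backward(self, dhs):
        x, hs, cache = self._cache
        bsz, T, _ = x.shape
        H = self.d_hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((bsz, H), dtype=DTYPE)
        dc_next = np.zeros((bsz, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g),
                 do * o * (1 - o)], axis=1).astype(DTYPE)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((bsz, H), dtype=DTYPE)
            self.wx.grad += x[:, t].T @ dgates
            self.wh.grad += h_prev.T @ dgates
            self.b.grad += dgates.sum(axis=0)
            dx[:, t] = dgates @ self.wx.value.T
            dh_next = dgates @ self.wh.value.T
        return dx
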