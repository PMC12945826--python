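"""Small NumPy deep-learning core: layers with explicit forward/backward passes.

Every layer caches what its backward pass needs on ``forward`` and accumulates
parameter gradients in-place, so a model is trained by calling ``forward``,
seeding the output gradient, and calling ``backward`` in reverse order.
Shapes follow the time-series convention ``(batch, time, channels)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "CausalDilatedConv1d",
    "LayerNorm",
    "ReLU",
    "Tanh",
    "SpatialDropout",
    "LSTM",
    "BiLSTM",
    "dilated_conv_1d",
    "receptive_field",
    "sigmoid",
    "softmax",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clipping keeps exp() in range; 1e-26 error at the clip bound is far
    # below float32 resolution
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Param:
    """A trainable array with its gradient and Adam moment buffers."""

    __slots__ = ("value", "grad", "m", "v", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) == 3:  # (kernel, in, out) convolution weights
        fan_in = shape[0] * shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense:
    """Affine map ``y = x @ W + b`` on the last axis of a 2-D input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "dense"):
        self.W = Param(_glorot(rng, (n_in, n_out), dtype), f"{name}.W")
        self.b = Param(np.zeros(n_out, dtype=dtype), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class CausalDilatedConv1d:
    """Length-preserving causal dilated convolution on ``(B, T, C)`` input.

    ``y[b, p, o] = b[o] + sum_{i, c} x[b, p - d*i, c] * W[i, c, o]`` with
    out-of-range input treated as zero, so no future sample leaks into the
    output and ``d = 1`` recovers the standard causal convolution.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator, dtype=np.float32, name: str = "conv"):
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        if kernel_size < 1:
            raise ValueError("kernel size must be >= 1")
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.W = Param(_glorot(rng, (kernel_size, c_in, c_out), dtype), f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        B, T, _ = x.shape
        y = np.broadcast_to(self.b.value, (B, T, self.b.value.shape[0])).copy()
        for i in range(self.kernel_size):
            s = self.dilation * i
            if s == 0:
                y += x @ self.W.value[i]
            elif s < T:
                y[:, s:, :] += x[:, :-s, :] @ self.W.value[i]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        T = x.shape[1]
        dx = np.zeros_like(x)
        for i in range(self.kernel_size):
            s = self.dilation * i
            if s == 0:
                self.W.grad[i] += np.tensordot(x, dy, axes=([0, 1], [0, 1]))
                dx += dy @ self.W.value[i].T
            elif s < T:
                self.W.grad[i] += np.tensordot(
                    x[:, :-s, :], dy[:, s:, :], axes=([0, 1], [0, 1])
                )
                dx[:, :-s, :] += dy[:, s:, :] @ self.W.value[i].T
        self.b.grad += dy.sum(axis=(0, 1))
        return dx


class LayerNorm:
    """Normalization over the channel axis at every (batch, time) position."""

    def __init__(self, n_channels: int, dtype=np.float32, eps: float = 1e-5,
                 name: str = "ln"):
        self.gamma = Param(np.ones(n_channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(n_channels, dtype=dtype), f"{name}.beta")
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        C = xhat.shape[-1]
        self.gamma.grad += (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        self.beta.grad += dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma.value
        return (inv_std / C) * (
            C * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Tanh:
    def __init__(self):
        self._y = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class SpatialDropout:
    """Channel-wise dropout: entire feature maps are zeroed per sample."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (rng.random((x.shape[0], 1, x.shape[2])) < keep) / keep
        self._mask = mask.astype(x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class LSTM:
    """Single-direction LSTM with standard input/forget/output gate algebra.

    Weights: ``Wx (D, 4H)``, ``Wh (H, 4H)``, bias ``(4H,)`` in gate order
    (input, forget, cell, output); the forget-gate bias section starts at 1.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "lstm"):
        H = hidden
        self.hidden = H
        self.Wx = Param(_glorot(rng, (n_in, 4 * H), dtype), f"{name}.Wx")
        self.Wh = Param(_glorot(rng, (H, 4 * H), dtype), f"{name}.Wh")
        b = np.zeros(4 * H, dtype=dtype)
        b[H : 2 * H] = 1.0
        self.b = Param(b, f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        dtype = x.dtype
        hs = np.zeros((B, T + 1, H), dtype=dtype)
        cs = np.zeros((B, T + 1, H), dtype=dtype)
        gates = np.zeros((B, T, 4 * H), dtype=dtype)
        tanh_c = np.zeros((B, T, H), dtype=dtype)
        xw = x @ self.Wx.value + self.b.value
        for t in range(T):
            a = xw[:, t] + hs[:, t] @ self.Wh.value
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = sigmoid(a[:, 3 * H :])
            c = f * cs[:, t] + i * g
            tc = np.tanh(c)
            hs[:, t + 1] = o * tc
            cs[:, t + 1] = c
            gates[:, t, :H] = i
            gates[:, t, H : 2 * H] = f
            gates[:, t, 2 * H : 3 * H] = g
            gates[:, t, 3 * H :] = o
            tanh_c[:, t] = tc
        self._cache = (x, hs, cs, gates, tanh_c)
        return hs[:, 1:]

    def backward(self, dys: np.ndarray) -> np.ndarray:
        x, hs, cs, gates, tanh_c = self._cache
        B, T, _ = x.shape
        H = self.hidden
        dx = np.zeros_like(x)
        da_all = np.zeros((B, T, 4 * H), dtype=x.dtype)
        dh = np.zeros((B, H), dtype=x.dtype)
        dc = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh + dys[:, t]
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = tanh_c[:, t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * g
            dg = dc * i
            df = dc * cs[:, t]
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            da_all[:, t] = da
            dh = da @ self.Wh.value.T
            dc = dc * f
        # batched parameter gradients
        self.Wx.grad += np.tensordot(x, da_all, axes=([0, 1], [0, 1]))
        self.Wh.grad += np.tensordot(hs[:, :-1], da_all, axes=([0, 1], [0, 1]))
        self.b.grad += da_all.sum(axis=(0, 1))
        dx += da_all @ self.Wx.value.T
        return dx


class BiLSTM:
    """Bidirectional LSTM: forward and time-reversed streams, concatenated.

    ``forward`` returns the per-step outputs ``(B, T, 2H)``; the first ``H``
    channels depend only on ``x[.. : t]``, the last ``H`` only on ``x[t : ..]``.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "bilstm"):
        self.hidden = hidden
        self.fwd = LSTM(n_in, hidden, rng, dtype, name=f"{name}.fwd")
        self.bwd = LSTM(n_in, hidden, rng, dtype, name=f"{name}.bwd")

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x[:, ::-1])
        return np.concatenate([yf, yb[:, ::-1]], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.hidden
        dxf = self.fwd.backward(np.ascontiguousarray(dy[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, H:]))
        return dxf + dxb[:, ::-1]


def dilated_conv_1d(F: np.ndarray, k: np.ndarray, d: int) -> np.ndarray:
    """Causal dilated convolution of a 1-D sequence with kernel ``k``.

    ``out[p] = sum_i F[p - d*i] * k[i]``, out-of-range terms zero, so the
    output has the input's length; ``d = 1`` is the standard discrete
    convolution (causal, zero-padded).
    """
    F = np.asarray(F, dtype=float)
    k = np.asarray(k, dtype=float)
    if F.ndim != 1 or F.size == 0:
        raise ValueError("input sequence must be non-empty and 1-D")
    if k.ndim != 1 or k.size == 0:
        raise ValueError("kernel must be non-empty and 1-D")
    if d < 1:
        raise ValueError("dilation must be >= 1")
    out = np.zeros_like(F)
    for i, ki in enumerate(k):
        s = d * i
        if s == 0:
            out += ki * F
        elif s < F.size:
            out[s:] += ki * F[:-s]
    return out


def receptive_field(kernel_size: int, dilations) -> int:
    """Receptive field of a stacked causal dilated-conv network."""
    return 1 + (kernel_size - 1) * int(np.sum(dilations))
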