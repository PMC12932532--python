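"""Layers with explicit forward/backward passes on (batch, length, channels)
float32 tensors.

Each layer exposes ``params`` and ``grads`` dicts (name -> array) and caches
whatever its backward pass needs during forward. ``trainable`` can be set
False to freeze a layer (its grads are still computed but skipped by the
optimizer)."""

from __future__ import annotations

import math

import numpy as np

F32 = np.float32


class Layer:
    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    limit = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Dense(Layer):
    """Pointwise affine map applied over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": _fan_in_uniform(rng, (d_in, d_out), d_in),
            "b": np.zeros(d_out, dtype=F32),
        }
        self.zero_grads()

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._x
        axes = tuple(range(x.ndim - 1))
        self.grads["W"] = np.tensordot(x, dout, axes=(axes, axes)).astype(F32)
        self.grads["b"] = dout.sum(axis=axes).astype(F32)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(F32)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(F32)


class LayerNorm(Layer):
    """Normalization over the time axis (default) or channel axis of a
    (batch, length, channels) tensor, with per-channel affine parameters.

    Normalizing over a single-channel axis would zero the signal entirely,
    which is why the time axis is the default for univariate inputs."""

    def __init__(self, n_channels: int, axis: str = "time",
                 eps: float = 1e-6) -> None:
        super().__init__()
        if axis not in ("time", "channels"):
            raise ValueError("axis must be 'time' or 'channels'")
        self.axis = 1 if axis == "time" else 2
        self.eps = eps
        self.params = {
            "gamma": np.ones(n_channels, dtype=F32),
            "beta": np.zeros(n_channels, dtype=F32),
        }
        self.zero_grads()

    def forward(self, x, *, training=False, rng=None):
        ax = self.axis
        mu = x.mean(axis=ax, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=ax, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = xc * self._inv
        return (self._xhat * self.params["gamma"] + self.params["beta"]).astype(F32)

    def backward(self, dout):
        ax = self.axis
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = np.einsum("blc,blc->c", dout, xhat).astype(F32)
        self.grads["beta"] = dout.sum(axis=(0, 1)).astype(F32)
        dxhat = dout * self.params["gamma"]
        m1 = dxhat.mean(axis=ax, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=ax, keepdims=True)
        return (inv * (dxhat - m1 - xhat * m2)).astype(F32)


def _softmax_last(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=-1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product multi-head self-attention with per-head key
    dimension ``head_size`` and an output projection back to the input
    channel count."""

    def __init__(self, c_in: int, num_heads: int, head_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.h, self.d = num_heads, head_size
        inner = num_heads * head_size
        self.params = {
            "Wq": _fan_in_uniform(rng, (c_in, inner), c_in),
            "Wk": _fan_in_uniform(rng, (c_in, inner), c_in),
            "Wv": _fan_in_uniform(rng, (c_in, inner), c_in),
            "bq": np.zeros(inner, dtype=F32),
            "bk": np.zeros(inner, dtype=F32),
            "bv": np.zeros(inner, dtype=F32),
            "Wo": _fan_in_uniform(rng, (inner, c_in), inner),
            "bo": np.zeros(c_in, dtype=F32),
        }
        self.zero_grads()

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, l, _ = x.shape
        return x.reshape(b, l, self.h, self.d).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, l, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, l, h * d)

    def forward(self, x, *, training=False, rng=None):
        p = self.params
        self._x = x
        q = self._split(x @ p["Wq"] + p["bq"])
        k = self._split(x @ p["Wk"] + p["bk"])
        v = self._split(x @ p["Wv"] + p["bv"])
        scale = 1.0 / math.sqrt(self.d)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = _softmax_last(scores)
        ctx = attn @ v
        self._cache = (q, k, v, attn, scale)
        merged = self._merge(ctx)
        self._merged = merged
        return (merged @ p["Wo"] + p["bo"]).astype(F32)

    @property
    def last_attention(self) -> np.ndarray:
        """(batch, heads, L, L) attention weights of the last forward."""
        return self._cache[3]

    def backward(self, dout):
        p = self.params
        q, k, v, attn, scale = self._cache
        x, merged = self._x, self._merged
        axes = ((0, 1), (0, 1))
        self.grads["Wo"] = np.tensordot(merged, dout, axes=axes).astype(F32)
        self.grads["bo"] = dout.sum(axis=(0, 1)).astype(F32)
        dctx = self._split(dout @ p["Wo"].T)
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= scale
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = np.zeros_like(x)
        for name, grad in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
            flat = self._merge(grad)
            self.grads[name] = np.tensordot(x, flat, axes=axes).astype(F32)
            self.grads["b" + name[1]] = flat.sum(axis=(0, 1)).astype(F32)
            dx += flat @ p[name].T
        return dx.astype(F32)


def _conv1d_same(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Cross-correlation with 'same' zero padding.

    x: (B, L, C_in); W: (k, C_in, C_out) -> (B, L, C_out)."""
    k = W.shape[0]
    pad_l, pad_r = (k - 1) // 2, k // 2
    xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B,L,C,k)
    return np.tensordot(win, W, axes=([3, 2], [0, 1]))


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.params = {
            "W": _fan_in_uniform(rng, (kernel, c_in, c_out), kernel * c_in),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.zero_grads()

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        return (_conv1d_same(x, self.params["W"]) + self.params["b"]).astype(F32)

    def backward(self, dout):
        W = self.params["W"]
        k = self.kernel
        x = self._x
        pad_l, pad_r = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # dW[j, ci, co] = sum_{b,l} x_pad[b, l+j, ci] * dout[b, l, co]
        dW = np.tensordot(win, dout, axes=([0, 1], [0, 1]))  # (C_in, k, C_out)
        self.grads["W"] = dW.transpose(1, 0, 2).astype(F32)
        self.grads["b"] = dout.sum(axis=(0, 1)).astype(F32)
        # dx = full correlation of dout with the flipped kernel, channels swapped
        W_adj = W[::-1].transpose(0, 2, 1)  # (k, C_out, C_in)
        dp = np.pad(dout, ((0, 0), (pad_r, pad_l), (0, 0)))
        dwin = np.lib.stride_tricks.sliding_window_view(dp, k, axis=1)
        return np.tensordot(dwin, W_adj, axes=([3, 2], [0, 1])).astype(F32)


class ConvTranspose1D(Layer):
    """Transposed 1-D convolution (stride 1, 'same'), the adjoint of
    :class:`Conv1D`: used as an upsampling/reconstruction layer. At stride
    1 it is computationally a convolution with the flipped kernel and
    swapped channel axes; the weight layout (k, C_in, C_out) matches the
    transposed-convolution convention."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.params = {
            "W": _fan_in_uniform(rng, (kernel, c_in, c_out), kernel * c_in),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.zero_grads()

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        k = self.kernel
        pad_l, pad_r = (k - 1) // 2, k // 2
        W_flip = self.params["W"][::-1]  # adjoint placement of taps
        xp = np.pad(x, ((0, 0), (pad_r, pad_l), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        y = np.tensordot(win, W_flip, axes=([3, 2], [0, 1]))
        return (y + self.params["b"]).astype(F32)

    def backward(self, dout):
        k = self.kernel
        pad_l, pad_r = (k - 1) // 2, k // 2
        x = self._x
        xp = np.pad(x, ((0, 0), (pad_r, pad_l), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        dWf = np.tensordot(win, dout, axes=([0, 1], [0, 1]))  # (C_in,k,C_out)
        self.grads["W"] = dWf.transpose(1, 0, 2)[::-1].astype(F32)
        self.grads["b"] = dout.sum(axis=(0, 1)).astype(F32)
        W_adj = self.params["W"][::-1].transpose(0, 2, 1)[::-1]  # (k,C_out,C_in)
        dp = np.pad(dout, ((0, 0), (pad_l, pad_r), (0, 0)))
        dwin = np.lib.stride_tricks.sliding_window_view(dp, k, axis=1)
        return np.tensordot(dwin, W_adj, axes=([3, 2], [0, 1])).astype(F32)


class GlobalAveragePooling(Layer):
    """Average a (B, L, C) tensor over time (-> B, C) or channels (-> B, L)."""

    def __init__(self, axis: str = "channels") -> None:
        super().__init__()
        if axis not in ("time", "channels"):
            raise ValueError("axis must be 'time' or 'channels'")
        self.axis = 1 if axis == "time" else 2

    def forward(self, x, *, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=self.axis).astype(F32)

    def backward(self, dout):
        n = self._shape[self.axis]
        return (np.expand_dims(dout, self.axis) / n * np.ones(self._shape, dtype=F32))
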