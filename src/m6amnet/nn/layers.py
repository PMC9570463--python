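"""Neural-network layers built on the autograd engine.

Every layer exposes ``params()`` returning its trainable tensors in a
fixed order, which is also the checkpoint serialization order.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, cat, glorot, unfold1d, zeros


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32):
        self.w = glorot(rng, (in_dim, out_dim), dtype)
        self.b = zeros((out_dim,), dtype, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class Conv1d:
    """'Valid' 1-D convolution over (batch, length, channels) input."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        self.kernel = kernel
        self.w = glorot(rng, (kernel * in_ch, out_ch), dtype)
        self.b = zeros((out_ch,), dtype, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return unfold1d(x, self.kernel) @ self.w + self.b

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention over sequence positions.

    Input (B, L, C) is projected to ``model_dim``; output is (B, L,
    model_dim) — the sequence length is always preserved.
    """

    def __init__(self, in_dim: int, model_dim: int, heads: int, rng: np.random.Generator, dtype=np.float32):
        if model_dim % heads != 0:
            raise ValueError(f"model_dim {model_dim} not divisible by heads {heads}")
        self.heads = heads
        self.model_dim = model_dim
        self.wq = glorot(rng, (in_dim, model_dim), dtype)
        self.wk = glorot(rng, (in_dim, model_dim), dtype)
        self.wv = glorot(rng, (in_dim, model_dim), dtype)
        self.wo = glorot(rng, (model_dim, model_dim), dtype)
        self.bq = zeros((model_dim,), dtype, requires_grad=True)
        self.bk = zeros((model_dim,), dtype, requires_grad=True)
        self.bv = zeros((model_dim,), dtype, requires_grad=True)
        self.bo = zeros((model_dim,), dtype, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        b, length, _ = x.shape
        h, dh = self.heads, self.model_dim // self.heads

        def split(t: Tensor) -> Tensor:  # (B, L, D) -> (B, H, L, dh)
            return t.reshape(b, length, h, dh).transpose(0, 2, 1, 3)

        q = split(x @ self.wq + self.bq)
        k = split(x @ self.wk + self.bk)
        v = split(x @ self.wv + self.bv)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, length, self.model_dim)
        return out @ self.wo + self.bo

    def params(self) -> list[Tensor]:
        return [self.wq, self.bq, self.wk, self.bk, self.wv, self.bv, self.wo, self.bo]


class _LSTMDirection:
    """One direction of an LSTM; returns the final hidden state."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.hidden = hidden
        self.wx = glorot(rng, (in_dim, 4 * hidden), dtype)
        self.wh = glorot(rng, (hidden, 4 * hidden), dtype)
        bias = np.zeros(4 * hidden, dtype=dtype)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(bias, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        b, length, _ = x.shape
        hid = self.hidden
        xp = x @ self.wx + self.b  # (B, L, 4H), precomputed for all steps
        h = zeros((b, hid), x.data.dtype)
        c = zeros((b, hid), x.data.dtype)
        for t in range(length):
            gates = xp[:, t, :] + h @ self.wh
            i = gates[:, :hid].sigmoid()
            f = gates[:, hid : 2 * hid].sigmoid()
            o = gates[:, 2 * hid : 3 * hid].sigmoid()
            u = gates[:, 3 * hid :].tanh()
            c = f * c + i * u
            h = o * c.tanh()
        return h

    def params(self) -> list[Tensor]:
        return [self.wx, self.wh, self.b]


class BiLSTM:
    """Bidirectional LSTM returning concatenated final states (B, 2*hidden)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.fwd = _LSTMDirection(in_dim, hidden, rng, dtype)
        self.bwd = _LSTMDirection(in_dim, hidden, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return cat([self.fwd(x), self.bwd(x[:, ::-1, :])], axis=1)

    def params(self) -> list[Tensor]:
        return self.fwd.params() + self.bwd.params()
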