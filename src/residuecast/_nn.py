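"""Neural-network building blocks for the forecasters.

Layers are thin containers of parameter tensors with a ``__call__``
building the autodiff graph.  Includes the differentiable counterparts
of the numpy-level series decomposition and auto-correlation operators
(same arithmetic, expressed in Tensor ops so gradients flow).
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat, softmax
from .autocorrelation import select_lags

__all__ = [
    "Linear", "Dropout", "FeedForward", "positional_encoding",
    "decomp_tensor", "AutoCorrelationLayer", "SoftmaxAttentionLayer",
    "RNNLayer", "LSTMLayer",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    def __init__(self, rng: np.random.Generator, fan_in: int, fan_out: int,
                 bias: bool = True):
        self.W = Tensor(_glorot(rng, fan_in, fan_out), requires_grad=True)
        self.b = Tensor(np.zeros(fan_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])


class Dropout:
    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        if not training or self.p <= 0.0:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)

    def parameters(self) -> list[Tensor]:
        return []


class FeedForward:
    """Position-wise two-layer MLP with ReLU."""

    def __init__(self, rng: np.random.Generator, d_model: int, d_ff: int,
                 dropout: float):
        self.lin1 = Linear(rng, d_model, d_ff)
        self.lin2 = Linear(rng, d_ff, d_model)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        return self.lin2(self.drop(self.lin1(x).relu(), rng, training))

    def parameters(self) -> list[Tensor]:
        return self.lin1.parameters() + self.lin2.parameters()


def positional_encoding(length: int, d_model: int) -> np.ndarray:
    """Sinusoidal day-index encoding, shape (length, d_model)."""
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def decomp_tensor(x: Tensor, kernel: int) -> tuple[Tensor, Tensor]:
    """Differentiable (seasonal, trend) decomposition of (B, L, D)
    sequences: centred moving average with edge replication along the
    time axis, seasonal = x - trend.  Same arithmetic as
    :func:`residuecast.decomposition.series_decomp`."""
    if kernel % 2 == 0:
        raise ValueError(f"kernel must be odd, got {kernel}")
    if kernel == 1:
        return x * 0.0, x * 1.0
    length = x.shape[1]
    half = (kernel - 1) // 2
    first = x[:, 0:1, :]
    last = x[:, length - 1:length, :]
    padded = concat([first] * half + [x] + [last] * half, axis=1)
    trend = padded[:, 0:length, :]
    for off in range(1, kernel):
        trend = trend + padded[:, off:off + length, :]
    trend = trend * (1.0 / kernel)
    return x - trend, trend


def _resample_time(t: Tensor, length: int) -> Tensor:
    """Truncate or zero-pad a (B, L, D) tensor along the time axis."""
    cur = t.shape[1]
    if cur == length:
        return t
    if cur > length:
        return t[:, 0:length, :]
    pad = Tensor(np.zeros((t.shape[0], length - cur, t.shape[2])))
    return concat([t, pad], axis=1)


class AutoCorrelationLayer:
    """Multi-head auto-correlation attention.

    Lag scoring follows the Wiener-Khinchin route: full per-lag circular
    correlation of projected queries and keys is computed by FFT
    (outside the graph, averaged over batch and channels per head) to
    pick the top ``floor(factor * ln L)`` lags; the scores at those lags
    are then recomputed differentiably per sample, softmax-weighted, and
    used to blend circularly rolled value copies (time-delay
    aggregation).
    """

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int,
                 factor: float, dropout: float):
        if d_model % n_heads:
            raise ValueError(f"model width {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.factor = factor
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)
        self.drop = Dropout(dropout)

    def __call__(self, q_in: Tensor, k_in: Tensor, v_in: Tensor,
                 rng: np.random.Generator, training: bool) -> Tensor:
        q = self.wq(q_in)
        k = _resample_time(self.wk(k_in), q.shape[1])
        v = _resample_time(self.wv(v_in), q.shape[1])
        length = q.shape[1]
        head_outs = []
        for h in range(self.n_heads):
            sl = slice(h * self.d_head, (h + 1) * self.d_head)
            qh = q[:, :, sl]
            kh = k[:, :, sl]
            vh = v[:, :, sl]
            # lag discovery: FFT correlation averaged over batch+channels
            fq = np.fft.rfft(qh.data, axis=1)
            fk = np.fft.rfft(kh.data, axis=1)
            corr = np.fft.irfft(np.conj(fq) * fk, n=length, axis=1)
            lag_scores = corr.mean(axis=(0, 2)) / length
            lags = select_lags(lag_scores, self.factor, length)
            # differentiable per-sample scores at the selected lags
            per_lag_scores = []
            rolled_values = []
            norm = 1.0 / (length * self.d_head)
            for tau in lags:
                kr = kh.roll(-int(tau), axis=1)
                s = (qh * kr).sum(axis=(1, 2)) * norm
                per_lag_scores.append(s.reshape(-1, 1))
                rolled_values.append(vh.roll(-int(tau), axis=1))
            weights = softmax(concat(per_lag_scores, axis=1), axis=1)  # (B, k)
            out_h = None
            for j in range(len(lags)):
                wj = weights[:, j:j + 1].reshape(-1, 1, 1)
                term = wj * rolled_values[j]
                out_h = term if out_h is None else out_h + term
            head_outs.append(out_h)
        out = concat(head_outs, axis=2)
        return self.drop(self.wo(out), rng, training)

    def parameters(self) -> list[Tensor]:
        return (self.wq.parameters() + self.wk.parameters()
                + self.wv.parameters() + self.wo.parameters())


class SoftmaxAttentionLayer:
    """Standard scaled dot-product multi-head attention (baseline)."""

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int,
                 dropout: float):
        if d_model % n_heads:
            raise ValueError(f"model width {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)
        self.drop = Dropout(dropout)

    def __call__(self, q_in: Tensor, k_in: Tensor, v_in: Tensor,
                 rng: np.random.Generator, training: bool) -> Tensor:
        q, k, v = self.wq(q_in), self.wk(k_in), self.wv(v_in)
        scale = 1.0 / np.sqrt(self.d_head)
        head_outs = []
        for h in range(self.n_heads):
            sl = slice(h * self.d_head, (h + 1) * self.d_head)
            qh, kh, vh = q[:, :, sl], k[:, :, sl], v[:, :, sl]
            scores = (qh @ kh.swapaxes(1, 2)) * scale   # (B, Lq, Lk)
            attn = softmax(scores, axis=-1)
            head_outs.append(attn @ vh)
        out = concat(head_outs, axis=2)
        return self.drop(self.wo(out), rng, training)

    def parameters(self) -> list[Tensor]:
        return (self.wq.parameters() + self.wk.parameters()
                + self.wv.parameters() + self.wo.parameters())


class RNNLayer:
    """Single-layer Elman recurrence over (B, L, F) inputs; returns the
    final hidden state (B, H)."""

    def __init__(self, rng: np.random.Generator, n_features: int, hidden: int):
        self.hidden = hidden
        self.wx = Linear(rng, n_features, hidden)
        self.wh = Linear(rng, hidden, hidden, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        batch, length = x.shape[0], x.shape[1]
        h = Tensor(np.zeros((batch, self.hidden)))
        for t in range(length):
            h = (self.wx(x[:, t, :]) + self.wh(h)).tanh()
        return h

    def parameters(self) -> list[Tensor]:
        return self.wx.parameters() + self.wh.parameters()


class LSTMLayer:
    """Single-layer LSTM over (B, L, F) inputs; returns the final hidden
    state (B, H).  Gates packed (input, forget, cell, output); forget
    bias initialised to 1."""

    def __init__(self, rng: np.random.Generator, n_features: int, hidden: int):
        self.hidden = hidden
        self.wx = Linear(rng, n_features, 4 * hidden)
        self.wh = Linear(rng, hidden, 4 * hidden, bias=False)
        self.wx.b.data[hidden:2 * hidden] = 1.0

    def __call__(self, x: Tensor) -> Tensor:
        batch, length = x.shape[0], x.shape[1]
        hd = self.hidden
        h = Tensor(np.zeros((batch, hd)))
        c = Tensor(np.zeros((batch, hd)))
        for t in range(length):
            z = self.wx(x[:, t, :]) + self.wh(h)
            i = z[:, 0:hd].sigmoid()
            f = z[:, hd:2 * hd].sigmoid()
            g = z[:, 2 * hd:3 * hd].tanh()
            o = z[:, 3 * hd:4 * hd].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h

    def parameters(self) -> list[Tensor]:
        return self.wx.parameters() + self.wh.parameters()
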