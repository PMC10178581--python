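"""Progressive-decomposition encoder-decoder forecaster.

The network interleaves moving-average series decomposition with
auto-correlation attention.  The encoder strips the trend at every
sublayer and refines the seasonal signal; the decoder runs two branches:
a seasonal branch of stacked auto-correlation blocks (self, then cross
against the encoder output, then feed-forward) and a trend branch that
accumulates the trend components shed by each decomposition through
learned per-layer linear projections.  The forecast is the projected
seasonal output plus the accumulated trend over the last ``horizon``
steps.

The decoder is initialised from the decomposition of the trailing
``label_length`` steps of the context: the seasonal part extended by
``horizon`` zeros, the trend part extended by the context mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._nn import (AutoCorrelationLayer, Dropout, FeedForward, Linear,
                  decomp_tensor, positional_encoding)
from ._tensor import Tensor, concat
from .decomposition import series_decomp

__all__ = ["ForecastModelConfig", "AutoformerNet", "prepare_decoder_input"]


@dataclass(frozen=True)
class ForecastModelConfig:
    """Architecture and training hyperparameters shared by the
    forecasters.

    Defaults are desk-scale (narrow width, one layer each way) so the
    whole comparison runs on a single CPU in minutes; widen for
    larger studies.
    """

    model_width: int = 32
    n_heads: int = 2
    n_encoder_layers: int = 1
    n_decoder_layers: int = 1
    feedforward_width: int = 64
    decomp_kernel: int = 9
    autocorr_factor: float = 1.0
    context_length: int = 14
    label_length: int = 7
    horizon: int = 7
    dropout: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.label_length > self.context_length:
            raise ValueError("label_length cannot exceed context_length")
        for name in ("model_width", "n_heads", "n_encoder_layers",
                     "n_decoder_layers", "feedforward_width", "context_length",
                     "label_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.decomp_kernel % 2 == 0:
            raise ValueError("decomp_kernel must be odd")


def prepare_decoder_input(context: np.ndarray, config: ForecastModelConfig
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Seasonal and trend initialisation for the decoder.

    Decomposes the last ``label_length`` steps of the (1-D) target
    context; the seasonal part is extended by ``horizon`` zeros and the
    trend part by ``horizon`` copies of the context mean.  Returns two
    arrays of length ``label_length + horizon``.
    """
    if config.horizon == 0:
        raise ValueError("horizon must be >= 1")
    context = np.asarray(context, dtype=np.float64).ravel()
    if len(context) < config.label_length:
        raise ValueError(
            f"context length {len(context)} < label_length {config.label_length}")
    tail = context[-config.label_length:]
    kernel = min(config.decomp_kernel, 2 * len(tail) - 1)
    if kernel % 2 == 0:
        kernel -= 1
    dec = series_decomp(tail, kernel)
    seasonal = np.concatenate([dec.seasonal, np.zeros(config.horizon)])
    trend = np.concatenate([dec.trend, np.full(config.horizon, context.mean())])
    return seasonal, trend


class _EncoderLayer:
    def __init__(self, rng, cfg: ForecastModelConfig):
        self.autocorr = AutoCorrelationLayer(rng, cfg.model_width, cfg.n_heads,
                                             cfg.autocorr_factor, cfg.dropout)
        self.ff = FeedForward(rng, cfg.model_width, cfg.feedforward_width, cfg.dropout)
        self.kernel = cfg.decomp_kernel

    def __call__(self, x, rng, training):
        s1, _ = decomp_tensor(x + self.autocorr(x, x, x, rng, training), self.kernel)
        s2, _ = decomp_tensor(s1 + self.ff(s1, rng, training), self.kernel)
        return s2

    def parameters(self):
        return self.autocorr.parameters() + self.ff.parameters()


class _DecoderLayer:
    def __init__(self, rng, cfg: ForecastModelConfig):
        self.self_ac = AutoCorrelationLayer(rng, cfg.model_width, cfg.n_heads,
                                            cfg.autocorr_factor, cfg.dropout)
        self.cross_ac = AutoCorrelationLayer(rng, cfg.model_width, cfg.n_heads,
                                             cfg.autocorr_factor, cfg.dropout)
        self.ff = FeedForward(rng, cfg.model_width, cfg.feedforward_width, cfg.dropout)
        self.proj1 = Linear(rng, cfg.model_width, 1, bias=False)
        self.proj2 = Linear(rng, cfg.model_width, 1, bias=False)
        self.proj3 = Linear(rng, cfg.model_width, 1, bias=False)
        self.kernel = cfg.decomp_kernel

    def __call__(self, s, trend, enc_out, rng, training):
        s1, t1 = decomp_tensor(s + self.self_ac(s, s, s, rng, training), self.kernel)
        s2, t2 = decomp_tensor(
            s1 + self.cross_ac(s1, enc_out, enc_out, rng, training), self.kernel)
        s3, t3 = decomp_tensor(s2 + self.ff(s2, rng, training), self.kernel)
        trend = trend + self.proj1(t1) + self.proj2(t2) + self.proj3(t3)
        return s3, trend

    def parameters(self):
        return (self.self_ac.parameters() + self.cross_ac.parameters()
                + self.ff.parameters() + self.proj1.parameters()
                + self.proj2.parameters() + self.proj3.parameters())


class AutoformerNet:
    """The assembled network operating on standardized window arrays.

    Inputs are ``(batch, context_length, n_features)`` with the target
    (concentration) in channel 0; outputs are ``(batch, horizon)``
    point forecasts of channel 0.
    """

    def __init__(self, config: ForecastModelConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(config.seed)
        cfg = config
        self.enc_embed = Linear(rng, n_features, cfg.model_width)
        self.dec_embed = Linear(rng, 1, cfg.model_width)
        self.enc_layers = [_EncoderLayer(rng, cfg) for _ in range(cfg.n_encoder_layers)]
        self.dec_layers = [_DecoderLayer(rng, cfg) for _ in range(cfg.n_decoder_layers)]
        self.head = Linear(rng, cfg.model_width, 1)
        self.enc_pos = positional_encoding(cfg.context_length, cfg.model_width)
        self.dec_pos = positional_encoding(cfg.label_length + cfg.horizon,
                                           cfg.model_width)

    def parameters(self) -> list[Tensor]:
        params = self.enc_embed.parameters() + self.dec_embed.parameters()
        for layer in self.enc_layers + self.dec_layers:
            params += layer.parameters()
        return params + self.head.parameters()

    # -- forward pieces -----------------------------------------------------
    def encode(self, x: np.ndarray, rng: np.random.Generator,
               training: bool) -> Tensor:
        """Embed the context and run the encoder stack; returns the
        final seasonal representation (B, Lc, model_width)."""
        if x.shape[1] != self.config.context_length:
            raise ValueError(
                f"context length {x.shape[1]} != configured "
                f"{self.config.context_length}")
        if x.shape[2] != self.n_features:
            raise ValueError(f"{x.shape[2]} features != expected {self.n_features}")
        h = self.enc_embed(Tensor(x)) + Tensor(self.enc_pos)
        for layer in self.enc_layers:
            h = layer(h, rng, training)
        return h

    def decode(self, seasonal_init: np.ndarray, trend_init: np.ndarray,
               enc_out: Tensor, rng: np.random.Generator,
               training: bool) -> tuple[Tensor, Tensor]:
        """Run the decoder stack; returns (seasonal_out, trend_out),
        both (B, label_length + horizon, ...)."""
        s = self.dec_embed(Tensor(seasonal_init[:, :, None])) + Tensor(self.dec_pos)
        trend = Tensor(trend_init[:, :, None])
        for layer in self.dec_layers:
            s, trend = layer(s, trend, enc_out, rng, training)
        return s, trend

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        """Full forward pass on a standardized window batch."""
        if rng is None:
            rng = np.random.default_rng(0)
        batch = x.shape[0]
        enc_out = self.encode(x, rng, training)
        seas = np.empty((batch, self.config.label_length + self.config.horizon))
        trend = np.empty_like(seas)
        for b in range(batch):
            seas[b], trend[b] = prepare_decoder_input(x[b, :, 0], self.config)
        s_out, t_out = self.decode(seas, trend, enc_out, rng, training)
        pred = self.head(s_out) + t_out
        return pred[:, -self.config.horizon:, 0]

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()
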