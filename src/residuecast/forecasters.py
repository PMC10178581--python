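"""Forecaster estimators with a scikit-learn-style fit/predict surface.

All forecasters operate on window arrays: ``X`` of shape
``(n_windows, context_length, n_features)`` (target concentration in
channel 0, covariates after) and ``y`` of shape ``(n_windows, horizon)``.
:func:`make_windows` slices such arrays out of a storage-record table,
standardizing the target per series with train-split statistics only
(covariates use global train statistics so cross-series climate
contrasts survive).

Estimators follow scikit-learn conventions: hyperparameters in
``__init__``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore, deterministic given ``random_state``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Dropout, LSTMLayer, Linear, RNNLayer, SoftmaxAttentionLayer, \
    FeedForward, positional_encoding
from ._tensor import Adam, Tensor, concat
from .autoformer import AutoformerNet, ForecastModelConfig

__all__ = [
    "make_windows", "WindowSet", "BaseWindowForecaster",
    "AutoformerForecaster", "RNNForecaster", "LSTMForecaster",
    "TransformerForecaster", "NaiveLastForecaster", "build_baseline",
    "train_forecaster", "forecast_all_days", "save_checkpoint", "load_checkpoint",
]

FEATURE_COLUMNS = ["concentration_mg_per_kg", "temperature_C", "humidity_pct"]


@dataclass
class WindowSet:
    """Standardized forecasting windows plus the bookkeeping needed to
    map predictions back to mg/kg."""

    X: np.ndarray               # (n, context, features), standardized
    y: np.ndarray               # (n, horizon), standardized target
    series_id: np.ndarray       # per-window series index
    origin_day: np.ndarray      # day of the last context observation
    scale: np.ndarray           # per-window (mean, sd) of the target's series
    pesticide: np.ndarray       # per-window pesticide name

    def destandardize(self, pred_std: np.ndarray) -> np.ndarray:
        mean = self.scale[:, 0:1]
        sd = self.scale[:, 1:2]
        return pred_std * sd + mean

    @property
    def y_raw(self) -> np.ndarray:
        return self.destandardize(self.y)


def _series_frames(dataset: pd.DataFrame) -> list[pd.DataFrame]:
    keys = ["pesticide", "temperature_C", "humidity_pct"]
    return [grp.sort_values("day", kind="stable").reset_index(drop=True)
            for _, grp in dataset.groupby(keys, sort=False)]


def make_windows(dataset: pd.DataFrame, context_length: int, horizon: int,
                 split: str = "train") -> WindowSet:
    """Slide (context, horizon) windows over every series of a split
    storage table.

    Train windows lie entirely inside the train region of their series.
    Test (or validation) windows have their whole horizon inside that
    region while the context may reach back into earlier data — the
    standard forecasting protocol, with no future leakage either way.
    The target is standardized per series by its train-region mean/sd;
    covariates by pooled train-region statistics across series.
    """
    if "split" not in dataset.columns:
        raise ValueError("dataset has no split assignment; call split_dataset first")
    frames = _series_frames(dataset)
    train_rows = dataset[dataset["split"] == "train"]
    cov_mean = train_rows[FEATURE_COLUMNS[1:]].mean().to_numpy(dtype=np.float64)
    cov_sd = train_rows[FEATURE_COLUMNS[1:]].std().to_numpy(dtype=np.float64)
    cov_sd[~np.isfinite(cov_sd) | (cov_sd == 0)] = 1.0

    xs, ys, sids, days, scales, pests = [], [], [], [], [], []
    skipped = []
    for sid, frame in enumerate(frames):
        conc = frame["concentration_mg_per_kg"].to_numpy(dtype=np.float64)
        cov = frame[FEATURE_COLUMNS[1:]].to_numpy(dtype=np.float64)
        splits = frame["split"].to_numpy()
        tr_mask = splits == "train"
        if not tr_mask.any():
            continue
        mean_c = conc[tr_mask].mean()
        sd_c = conc[tr_mask].std()
        if sd_c == 0:
            sd_c = 1.0
        feat = np.column_stack([(conc - mean_c) / sd_c, (cov - cov_mean) / cov_sd])
        n = len(frame)
        region = np.flatnonzero(splits == split)
        found = False
        for end in range(context_length - 1, n - horizon):
            target_idx = np.arange(end + 1, end + 1 + horizon)
            if split == "train":
                window_ok = tr_mask[end - context_length + 1: end + 1 + horizon].all()
            else:
                window_ok = np.isin(target_idx, region).all()
            if not window_ok:
                continue
            found = True
            xs.append(feat[end - context_length + 1: end + 1])
            ys.append(feat[target_idx, 0])
            sids.append(sid)
            days.append(int(frame["day"].iloc[end]))
            scales.append((mean_c, sd_c))
            pests.append(frame["pesticide"].iloc[0])
        if not found:
            skipped.append(
                f"{frame['pesticide'].iloc[0]}@T={frame['temperature_C'].iloc[0]},"
                f"H={frame['humidity_pct'].iloc[0]} (n={n})")
    if not xs:
        raise ValueError(
            f"no valid ({context_length}+{horizon})-day windows in split "
            f"{split!r}; offending series: {skipped}")
    return WindowSet(X=np.asarray(xs), y=np.asarray(ys),
                     series_id=np.asarray(sids), origin_day=np.asarray(days),
                     scale=np.asarray(scales), pesticide=np.asarray(pests))


class BaseWindowForecaster:
    """Shared fit/predict machinery for the gradient-trained forecasters.

    Training uses Adam with a per-epoch exponential learning-rate decay
    (``lr_decay``) and global gradient-norm clipping (``clip_norm``) —
    both stabilise the small-batch training runs across seeds.
    """

    _param_names: tuple[str, ...] = ()
    lr_decay: float = 0.97
    clip_norm: float = 5.0
    _holdout_stride: int = 7  # every 7th window becomes early-stop holdout

    @classmethod
    def _clip_gradients(cls, params) -> None:
        if cls.clip_norm is None:
            return
        total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params
                            if p.grad is not None))
        if total > cls.clip_norm:
            scale = cls.clip_norm / total
            for p in params:
                if p.grad is not None:
                    p.grad *= scale

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self

    # subclasses implement _build(n_features) -> None and
    # _forward(X, rng, training) -> Tensor of shape (B, horizon)
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None):
        """Mini-batch MSE training.

        When no explicit validation windows are supplied, a
        deterministic holdout (every seventh window, spread across
        series and time) is carved out of the training windows; the
        parameters from the epoch with the lowest holdout loss are
        restored at the end, guarding against late-training divergence.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3 or y.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, context, features) and y (n, horizon)")
        if y.shape[1] != self.horizon:
            raise ValueError(f"y horizon {y.shape[1]} != configured {self.horizon}")
        if X_val is None and len(X) >= 3 * self._holdout_stride:
            held = np.arange(len(X)) % self._holdout_stride == self._holdout_stride // 2
            X, y, X_val, y_val = X[~held], y[~held], X[held], y[held]
        self.n_features_in_ = X.shape[2]
        self._build(X.shape[2])
        params = self._parameters()
        opt = Adam(params, lr=self.learning_rate)
        batch_rng = np.random.default_rng(self.random_state + 1)
        drop_rng = np.random.default_rng(self.random_state + 2)
        n = len(X)
        self.loss_trace_ = []
        self.val_loss_trace_ = []
        best = None
        for _ in range(self.epochs):
            order = batch_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = self._forward(X[idx], drop_rng, training=True)
                diff = pred - Tensor(y[idx])
                loss = (diff * diff).mean()
                opt.zero_grad()
                loss.backward()
                self._clip_gradients(params)
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            opt.lr *= self.lr_decay
            self.loss_trace_.append(epoch_loss / n)
            if X_val is not None:
                vp = self._forward(X_val, drop_rng, training=False).data
                vloss = float(np.mean((vp - y_val) ** 2))
                self.val_loss_trace_.append(vloss)
                if best is None or vloss < best[0]:
                    best = (vloss, len(self.loss_trace_),
                            [p.data.copy() for p in params])
        if best is not None:
            self.best_epoch_ = best[1]
            for p, data in zip(params, best[2]):
                p.data = data
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "loss_trace_"):
            raise ValueError(f"{type(self).__name__} is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != self.context_length:
            raise ValueError(
                f"X must be (n, {self.context_length}, features), got {X.shape}")
        rng = np.random.default_rng(0)  # dropout is off in eval mode
        return self._forward(X, rng, training=False).data.copy()


class AutoformerForecaster(BaseWindowForecaster):
    """Decomposition + auto-correlation forecaster (the main model)."""

    _param_names = ("context_length", "label_length", "horizon", "model_width",
                    "n_heads", "n_encoder_layers", "n_decoder_layers",
                    "feedforward_width", "decomp_kernel", "autocorr_factor",
                    "dropout", "epochs", "batch_size", "learning_rate",
                    "random_state")

    def __init__(self, context_length: int = 14, label_length: int = 7,
                 horizon: int = 7, model_width: int = 32, n_heads: int = 2,
                 n_encoder_layers: int = 1, n_decoder_layers: int = 1,
                 feedforward_width: int = 64, decomp_kernel: int = 9,
                 autocorr_factor: float = 1.0, dropout: float = 0.05,
                 epochs: int = 10, batch_size: int = 64,
                 learning_rate: float = 5e-3, random_state: int = 0):
        self.context_length = context_length
        self.label_length = label_length
        self.horizon = horizon
        self.model_width = model_width
        self.n_heads = n_heads
        self.n_encoder_layers = n_encoder_layers
        self.n_decoder_layers = n_decoder_layers
        self.feedforward_width = feedforward_width
        self.decomp_kernel = decomp_kernel
        self.autocorr_factor = autocorr_factor
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def model_config(self) -> ForecastModelConfig:
        return ForecastModelConfig(
            model_width=self.model_width, n_heads=self.n_heads,
            n_encoder_layers=self.n_encoder_layers,
            n_decoder_layers=self.n_decoder_layers,
            feedforward_width=self.feedforward_width,
            decomp_kernel=self.decomp_kernel,
            autocorr_factor=self.autocorr_factor,
            context_length=self.context_length, label_length=self.label_length,
            horizon=self.horizon, dropout=self.dropout, seed=self.random_state)

    def _build(self, n_features: int) -> None:
        self.net_ = AutoformerNet(self.model_config(), n_features)

    def _parameters(self):
        return self.net_.parameters()

    def _forward(self, X, rng, training):
        return self.net_.forward(X, rng, training)


class _RecurrentForecaster(BaseWindowForecaster):
    """Recurrent encoder + linear head mapping the final state to the
    horizon.

    The head predicts the deviation from the last observed target value
    (a skip connection), so the untrained network starts at the naive
    repeat-last forecast and learns the decay correction on top — this
    keeps the recurrent baselines well-behaved when the test range lies
    below everything seen in training."""

    _param_names = ("context_length", "horizon", "model_width", "epochs",
                    "batch_size", "learning_rate", "random_state")
    _cell_cls = RNNLayer

    def __init__(self, context_length: int = 14, horizon: int = 7,
                 model_width: int = 32, epochs: int = 10, batch_size: int = 64,
                 learning_rate: float = 5e-3, random_state: int = 0):
        self.context_length = context_length
        self.horizon = horizon
        self.model_width = model_width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _build(self, n_features: int) -> None:
        rng = np.random.default_rng(self.random_state)
        self.cell_ = self._cell_cls(rng, n_features, self.model_width)
        self.head_ = Linear(rng, self.model_width, self.horizon)

    def _parameters(self):
        return self.cell_.parameters() + self.head_.parameters()

    def _forward(self, X, rng, training):
        delta = self.head_(self.cell_(Tensor(X)))
        return delta + Tensor(X[:, -1, 0:1])


class RNNForecaster(_RecurrentForecaster):
    """Elman RNN baseline."""

    _cell_cls = RNNLayer


class LSTMForecaster(_RecurrentForecaster):
    """LSTM baseline."""

    _cell_cls = LSTMLayer


class TransformerForecaster(BaseWindowForecaster):
    """Standard encoder-decoder attention baseline with the same
    embedding, width, and horizon as the main model."""

    _param_names = ("context_length", "label_length", "horizon", "model_width",
                    "n_heads", "feedforward_width", "dropout", "epochs",
                    "batch_size", "learning_rate", "random_state")

    def __init__(self, context_length: int = 14, label_length: int = 7,
                 horizon: int = 7, model_width: int = 32, n_heads: int = 2,
                 feedforward_width: int = 64, dropout: float = 0.05,
                 epochs: int = 10, batch_size: int = 64,
                 learning_rate: float = 5e-3, random_state: int = 0):
        self.context_length = context_length
        self.label_length = label_length
        self.horizon = horizon
        self.model_width = model_width
        self.n_heads = n_heads
        self.feedforward_width = feedforward_width
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _build(self, n_features: int) -> None:
        rng = np.random.default_rng(self.random_state)
        w, h, d = self.model_width, self.n_heads, self.dropout
        self.enc_embed_ = Linear(rng, n_features, w)
        self.dec_embed_ = Linear(rng, 1, w)
        self.enc_attn_ = SoftmaxAttentionLayer(rng, w, h, d)
        self.enc_ff_ = FeedForward(rng, w, self.feedforward_width, d)
        self.dec_self_ = SoftmaxAttentionLayer(rng, w, h, d)
        self.dec_cross_ = SoftmaxAttentionLayer(rng, w, h, d)
        self.dec_ff_ = FeedForward(rng, w, self.feedforward_width, d)
        self.head_ = Linear(rng, w, 1)
        self.enc_pos_ = positional_encoding(self.context_length, w)
        self.dec_pos_ = positional_encoding(self.label_length + self.horizon, w)

    def _parameters(self):
        params = (self.enc_embed_.parameters() + self.dec_embed_.parameters()
                  + self.enc_attn_.parameters() + self.enc_ff_.parameters()
                  + self.dec_self_.parameters() + self.dec_cross_.parameters()
                  + self.dec_ff_.parameters() + self.head_.parameters())
        return params

    def _forward(self, X, rng, training):
        h = self.enc_embed_(Tensor(X)) + Tensor(self.enc_pos_)
        h = h + self.enc_attn_(h, h, h, rng, training)
        enc = h + self.enc_ff_(h, rng, training)
        # decoder input: label-length tail of the target plus a zero
        # placeholder for the horizon
        tail = X[:, -self.label_length:, 0:1]
        placeholder = np.concatenate(
            [tail, np.zeros((X.shape[0], self.horizon, 1))], axis=1)
        s = self.dec_embed_(Tensor(placeholder)) + Tensor(self.dec_pos_)
        s = s + self.dec_self_(s, s, s, rng, training)
        s = s + self.dec_cross_(s, enc, enc, rng, training)
        s = s + self.dec_ff_(s, rng, training)
        return self.head_(s)[:, -self.horizon:, 0]


class NaiveLastForecaster:
    """Repeat the last observed value over the whole horizon.

    The no-skill reference every trained model must beat.
    """

    def __init__(self, context_length: int = 14, horizon: int = 7):
        self.context_length = context_length
        self.horizon = horizon

    def get_params(self, deep: bool = True) -> dict:
        return {"context_length": self.context_length, "horizon": self.horizon}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        self.loss_trace_ = []
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.repeat(X[:, -1, 0:1], self.horizon, axis=1)


_BASELINES = {"rnn": RNNForecaster, "lstm": LSTMForecaster,
              "transformer": TransformerForecaster}


def build_baseline(kind: str, **params):
    """Construct a baseline forecaster sharing the train/forecast
    interface of the main model."""
    try:
        cls = _BASELINES[kind.lower()]
    except KeyError:
        raise ValueError(
            f"unknown baseline {kind!r}; options: {sorted(_BASELINES)}") from None
    valid = cls().get_params()
    return cls(**{k: v for k, v in params.items() if k in valid})


def train_forecaster(estimator, dataset: pd.DataFrame,
                     use_validation: bool = False):
    """Fit an estimator on the train-split windows of a storage table."""
    train = make_windows(dataset, estimator.context_length, estimator.horizon,
                         split="train")
    if use_validation:
        try:
            val = make_windows(dataset, estimator.context_length,
                               estimator.horizon, split="validation")
            estimator.fit(train.X, train.y, val.X, val.y)
            return estimator
        except ValueError:
            pass
    estimator.fit(train.X, train.y)
    return estimator


def forecast_all_days(estimator, dataset: pd.DataFrame
                      ) -> pd.DataFrame:
    """Horizon forecasts, in mg/kg, for every day of every series that
    has a full context behind it and a full horizon ahead.

    Returns a long frame: ``pesticide, temperature_C, humidity_pct,
    origin_day, step, predicted_mg_per_kg`` where step j predicts day
    ``origin_day + j``.
    """
    frames = _series_frames(dataset)
    train_rows = dataset[dataset["split"] == "train"] if "split" in dataset else dataset
    cov_mean = train_rows[FEATURE_COLUMNS[1:]].mean().to_numpy(dtype=np.float64)
    cov_sd = train_rows[FEATURE_COLUMNS[1:]].std().to_numpy(dtype=np.float64)
    cov_sd[~np.isfinite(cov_sd) | (cov_sd == 0)] = 1.0
    Lc, H = estimator.context_length, estimator.horizon
    records = []
    for frame in frames:
        conc = frame["concentration_mg_per_kg"].to_numpy(dtype=np.float64)
        cov = frame[FEATURE_COLUMNS[1:]].to_numpy(dtype=np.float64)
        if "split" in frame:
            tr = frame["split"].to_numpy() == "train"
            mean_c = conc[tr].mean() if tr.any() else conc.mean()
            sd_c = conc[tr].std() if tr.any() else conc.std()
        else:
            mean_c, sd_c = conc.mean(), conc.std()
        if sd_c == 0:
            sd_c = 1.0
        feat = np.column_stack([(conc - mean_c) / sd_c, (cov - cov_mean) / cov_sd])
        n = len(frame)
        ends = range(Lc - 1, n - H)
        X = np.asarray([feat[e - Lc + 1:e + 1] for e in ends])
        if len(X) == 0:
            continue
        pred = estimator.predict(X) * sd_c + mean_c
        pred = np.clip(pred, 0.0, None)
        for row, e in enumerate(ends):
            day = int(frame["day"].iloc[e])
            for j in range(H):
                records.append((frame["pesticide"].iloc[0],
                                frame["temperature_C"].iloc[0],
                                frame["humidity_pct"].iloc[0],
                                day, j + 1, pred[row, j]))
    return pd.DataFrame(records, columns=[
        "pesticide", "temperature_C", "humidity_pct", "origin_day", "step",
        "predicted_mg_per_kg"])


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(estimator, path) -> None:
    """Single-archive checkpoint: estimator class, hyperparameters, and
    parameter arrays."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(estimator._parameters())} \
        if isinstance(estimator, BaseWindowForecaster) else {}
    meta = json.dumps({
        "class": type(estimator).__name__,
        "params": estimator.get_params(),
        "n_features_in": getattr(estimator, "n_features_in_", None),
    })
    np.savez(path, meta=np.array(meta), **arrays)


def load_checkpoint(path):
    """Restore a forecaster saved by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    classes = {cls.__name__: cls for cls in
               (AutoformerForecaster, RNNForecaster, LSTMForecaster,
                TransformerForecaster, NaiveLastForecaster)}
    est = classes[meta["class"]](**meta["params"])
    if isinstance(est, BaseWindowForecaster):
        est.n_features_in_ = meta["n_features_in"]
        est._build(meta["n_features_in"])
        for p, a in zip(est._parameters(), arrays):
            p.data = np.asarray(a, dtype=np.float64)
        est.loss_trace_ = []
    else:
        est.fit(None)
    return est
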