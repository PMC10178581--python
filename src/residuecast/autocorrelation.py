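"""FFT-based auto-correlation scoring and time-delay aggregation.

The attention-like operator at the heart of the forecaster: lags are
scored by the circular cross-correlation of query and key (computed in
the frequency domain via the Wiener-Khinchin relation), the top
``floor(factor * ln L)`` lags are kept, and the value sequence is
aggregated as a softmax-weighted sum of circularly rolled copies that
aligns phase-similar sub-periods.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "autocorr_scores",
    "select_lags",
    "time_delay_aggregate",
    "resample_to_length",
]


def resample_to_length(seq: np.ndarray, length: int) -> np.ndarray:
    """Truncate or zero-pad ``seq`` along axis 0 to ``length`` rows."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.shape[0] >= length:
        return seq[:length]
    pad = np.zeros((length - seq.shape[0],) + seq.shape[1:], dtype=np.float64)
    return np.concatenate([seq, pad], axis=0)


def autocorr_scores(query: np.ndarray, key: np.ndarray) -> np.ndarray:
    """Lagged circular correlation of query against key.

    For each lag tau in {0, ..., L-1}::

        R(tau) = (1/L) * sum_t  query[t] . key[(t + tau) mod L]

    averaged over channels, computed in O(L log L) via FFT (the
    conjugate is taken on the query transform so that the time-domain
    identity above holds as written).  For ``query is key`` (real
    self-correlation) the score at lag 0 is the maximum.

    Parameters
    ----------
    query, key : arrays of shape (L,) or (L, d)
        Same length and channel count.  A key produced from a
        different-length source must be passed through
        :func:`resample_to_length` first.
    """
    query = np.atleast_2d(np.asarray(query, dtype=np.float64).T).T
    key = np.atleast_2d(np.asarray(key, dtype=np.float64).T).T
    if query.shape != key.shape:
        raise ValueError(f"query shape {query.shape} != key shape {key.shape}")
    length = query.shape[0]
    fq = np.fft.rfft(query, axis=0)
    fk = np.fft.rfft(key, axis=0)
    corr = np.fft.irfft(np.conj(fq) * fk, n=length, axis=0)
    return corr.mean(axis=1) / length


def select_lags(scores: np.ndarray, factor: float, length: int) -> np.ndarray:
    """Top-k lags by score with ``k = floor(factor * ln L)``, clipped to
    [1, L]; ties broken in favour of the smaller lag.  Lag 0 is eligible.

    Returns the selected lags sorted ascending.
    """
    scores = np.asarray(scores, dtype=np.float64)
    k = int(np.floor(factor * np.log(length)))
    k = min(k, length)
    if k < 1:
        raise ValueError(
            f"factor {factor} with L={length} gives k={k} < 1 selected lags"
        )
    # stable sort on (-score, lag): highest score first, smaller lag on ties
    order = np.lexsort((np.arange(len(scores)), -scores))
    return np.sort(order[:k])


def time_delay_aggregate(values: np.ndarray, lags: np.ndarray,
                         lag_scores: np.ndarray) -> np.ndarray:
    """Softmax-weighted sum of circularly rolled copies of ``values``.

    ``weights = softmax(lag_scores)``; the copy for lag tau places the
    value from position ``(t + tau) mod L`` at position ``t``, so the
    output at each time step blends the phase-aligned sub-periods.  The
    roll is circular, which preserves the per-channel mean exactly.
    """
    values = np.asarray(values, dtype=np.float64)
    lags = np.asarray(lags, dtype=int)
    lag_scores = np.asarray(lag_scores, dtype=np.float64)
    if lags.size == 0:
        raise ValueError("empty lag set")
    if lags.min() < 0 or lags.max() >= values.shape[0]:
        raise ValueError(f"lags must lie in [0, {values.shape[0] - 1}]")
    shifted = lag_scores - lag_scores.max()
    weights = np.exp(shifted)
    weights /= weights.sum()
    out = np.zeros_like(values, dtype=np.float64)
    for tau, w in zip(lags, weights):
        out += w * np.roll(values, -int(tau), axis=0)
    return out
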