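"""Moving-average series decomposition.

Splits a sequence into a slowly varying trend-cyclical part (a centred
moving average over an edge-padded copy of the series) and a seasonal
residual.  The decomposition is additive and exact: ``seasonal + trend``
reconstructs the input elementwise.  Multichannel inputs are decomposed
channel-independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DecompositionResult", "moving_average", "series_decomp"]

DEFAULT_KERNEL = 25


@dataclass(frozen=True)
class DecompositionResult:
    """Seasonal and trend components; ``seasonal + trend == input`` exactly."""

    seasonal: np.ndarray
    trend: np.ndarray


def _validate_kernel(kernel: int, length: int) -> None:
    if kernel % 2 == 0:
        raise ValueError(f"kernel must be odd (got {kernel}): centred window undefined")
    if kernel < 1 or kernel > 2 * length - 1:
        raise ValueError(f"kernel must be in [1, 2L-1] = [1, {2 * length - 1}], got {kernel}")


def moving_average(series: np.ndarray, kernel: int) -> np.ndarray:
    """Centred moving average with edge-replication padding.

    Parameters
    ----------
    series : array of shape (L,) or (L, d)
        Input sequence; channels along the last axis.
    kernel : int
        Odd window length, ``1 <= kernel <= 2L - 1``.

    Returns
    -------
    array of the same shape: ``out[i]`` is the mean of the kernel-wide
    window centred at ``i`` over the series padded by replicating the
    first and last element ``(kernel - 1) // 2`` times at each end.
    """
    series = np.asarray(series, dtype=np.float64)
    length = series.shape[0]
    _validate_kernel(kernel, length)
    if kernel == 1:
        return series.copy()
    half = (kernel - 1) // 2
    padded = np.concatenate(
        [np.repeat(series[:1], half, axis=0), series, np.repeat(series[-1:], half, axis=0)],
        axis=0,
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, kernel, axis=0)
    return windows.mean(axis=-1)


def series_decomp(series: np.ndarray, kernel: int) -> DecompositionResult:
    """Decompose ``series`` into (seasonal, trend) with ``trend`` the moving
    average and ``seasonal = series - trend``."""
    series = np.asarray(series, dtype=np.float64)
    trend = moving_average(series, kernel)
    return DecompositionResult(seasonal=series - trend, trend=trend)
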