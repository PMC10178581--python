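"""Head-to-head comparison of the forecasting models.

Trains each requested model on the train split, evaluates pooled
horizon forecasts on the test split in mg/kg, and tabulates the five
error metrics with exact pairwise differences — the same layout as a
published model-comparison error table.
"""

from __future__ import annotations

import pandas as pd

from .forecasters import (AutoformerForecaster, NaiveLastForecaster,
                          build_baseline, make_windows)
from .metrics import ComparisonTable, MetricReport, compute_metrics

__all__ = ["compare_models", "DEFAULT_MODEL_SET"]

DEFAULT_MODEL_SET = ("RNN", "LSTM", "Transformer", "Autoformer")


def _make_model(name: str, config: dict, seed: int):
    lname = name.lower()
    if lname == "autoformer":
        valid = AutoformerForecaster().get_params()
        return AutoformerForecaster(
            **{k: v for k, v in config.items() if k in valid}
        ).set_params(random_state=seed)
    if lname == "naive":
        return NaiveLastForecaster(
            context_length=config.get("context_length", 14),
            horizon=config.get("horizon", 7))
    model = build_baseline(lname, **config)
    return model.set_params(random_state=seed)


def compare_models(dataset: pd.DataFrame,
                   model_names=DEFAULT_MODEL_SET,
                   config: dict | None = None,
                   seed: int = 0) -> ComparisonTable:
    """Train and evaluate each named model on a split storage table.

    All models share the window geometry (context, horizon) and width
    from ``config`` for a fair comparison, differing only in
    architecture.  Metrics are computed on de-standardized (mg/kg)
    predictions pooled over all test windows.
    """
    config = dict(config or {})
    context = config.get("context_length", 14)
    horizon = config.get("horizon", 7)
    test = make_windows(dataset, context, horizon, split="test")
    reports: dict[str, MetricReport] = {}
    for name in model_names:
        model = _make_model(name, config, seed)
        train = make_windows(dataset, context, horizon, split="train")
        model.fit(train.X, train.y)
        pred = test.destandardize(model.predict(test.X))
        reports[name] = compute_metrics(pred.ravel(), test.y_raw.ravel())
    return ComparisonTable(reports)
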