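"""Forecast error metrics and model comparison tables.

MAE, MSE, RMSE, MAPE and SMAPE.  The percentage metrics are reported as
decimals by default (a MAPE of 0.04681 means 4.681%); pass
``as_percent=True`` for the x100 display convention.  SMAPE uses the
standard symmetric denominator (|pred| + |true|) / 2; a literal mode
with a minus sign in the denominator exists for audit only — it blows
up as predictions approach the truth and is never the default.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = ["MetricReport", "ComparisonTable", "compute_metrics"]

METRIC_NAMES = ("MAE", "MSE", "RMSE", "MAPE", "SMAPE")


@dataclass(frozen=True)
class MetricReport:
    """The five forecast error metrics plus the evaluated point count."""

    mae: float
    mse: float
    rmse: float
    mape: float
    smape: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"MAE": self.mae, "MSE": self.mse, "RMSE": self.rmse,
                "MAPE": self.mape, "SMAPE": self.smape}


def compute_metrics(predictions, truths, *, as_percent: bool = False,
                    strict_minus_smape: bool = False) -> MetricReport:
    """Elementwise error metrics between predictions and ground truth.

    Points with a zero truth are excluded from MAPE (with a warning and
    an adjusted n); if every truth is zero, MAPE is undefined and an
    error is raised.

    Parameters
    ----------
    predictions, truths : 1-D sequences of equal nonzero length.
    as_percent : multiply MAPE and SMAPE by 100 for display.
    strict_minus_smape : audit mode computing the symmetric denominator
        as (|pred| - |true|) / 2 literally instead of the standard plus.
    """
    pred = np.asarray(predictions, dtype=np.float64).ravel()
    true = np.asarray(truths, dtype=np.float64).ravel()
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError(
            f"predictions and truths must be equal nonzero length, got "
            f"{pred.shape} vs {true.shape}")
    err = pred - true
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    rmse = float(np.sqrt(mse))

    nonzero = true != 0
    if not nonzero.any():
        raise ValueError("MAPE undefined: all truths are zero")
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        warnings.warn(f"MAPE: dropped {n_dropped} zero-truth point(s)", stacklevel=2)
    mape = float(np.mean(np.abs(err[nonzero] / true[nonzero])))

    denom_sign = -1.0 if strict_minus_smape else 1.0
    denom = (np.abs(pred) + denom_sign * np.abs(true)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.abs(err) / denom
    smape = float(np.mean(terms))

    scale = 100.0 if as_percent else 1.0
    return MetricReport(mae=mae, mse=mse, rmse=rmse, mape=mape * scale,
                        smape=smape * scale, n=int(pred.size))


class ComparisonTable:
    """Per-model metric reports with exact pairwise differences.

    Mirrors the layout of a model-comparison error table:
    ``model, MAE, MSE, RMSE, MAPE, SMAPE`` at 5-decimal precision.
    """

    def __init__(self, reports: dict[str, MetricReport]):
        if not reports:
            raise ValueError("need at least one model report")
        self.reports = dict(reports)

    def difference(self, model_a: str, model_b: str) -> dict[str, float]:
        """Metric-wise ``model_a - model_b`` (exact subtraction of the
        stored values)."""
        a, b = self.reports[model_a].as_dict(), self.reports[model_b].as_dict()
        return {m: a[m] - b[m] for m in METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model": name, **rep.as_dict()} for name, rep in self.reports.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.5f")

    @classmethod
    def from_csv(cls, path_or_buf) -> "ComparisonTable":
        df = pd.read_csv(path_or_buf)
        reports = {}
        for _, row in df.iterrows():
            reports[row["model"]] = MetricReport(
                mae=row["MAE"], mse=row["MSE"], rmse=row["RMSE"],
                mape=row["MAPE"], smape=row["SMAPE"],
                n=int(row["n"]) if "n" in row and not pd.isna(row.get("n")) else 0)
        return cls(reports)

    @classmethod
    def from_values(cls, table: dict[str, dict[str, float]]) -> "ComparisonTable":
        """Build from already-computed metric values, e.g. a printed
        error table whose internal arithmetic is to be checked."""
        reports = {
            name: MetricReport(mae=vals["MAE"], mse=vals["MSE"], rmse=vals["RMSE"],
                               mape=vals["MAPE"], smape=vals["SMAPE"], n=0)
            for name, vals in table.items()
        }
        return cls(reports)
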