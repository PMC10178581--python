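"""End-to-end pipeline: simulate -> train -> forecast -> assess -> compare.

Every stage writes its artifact (dataset CSV, forecast CSV, metric CSV,
cluster reports) into the report directory, plus a JSON manifest with
the config hash, per-stage seeds and row counts.  Re-running with an
identical config reproduces identical artifacts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rcio
from .comparison import compare_models
from .forecasters import AutoformerForecaster, forecast_all_days, train_forecaster
from .quality import assign_quality_levels, build_quality_index, select_k
from .synthetic import build_dataset, flag_over_limit, split_dataset

__all__ = ["run_pipeline", "simulate_stage", "assess_stage"]

logger = logging.getLogger(__name__)


def simulate_stage(cfg: dict) -> pd.DataFrame:
    seed = rcio.stage_seed(cfg["seed"], "simulate")
    dataset = build_dataset(
        rcio.kinetic_params_from_config(cfg),
        rcio.conditions_from_config(cfg),
        n_days=cfg["synthetic"]["n_days"], seed=seed)
    return split_dataset(dataset, tuple(cfg["synthetic"]["ratios"]))


def _quality_tables(dataset: pd.DataFrame, forecasts: pd.DataFrame,
                    n: int) -> dict[str, pd.DataFrame]:
    """Per-pesticide quality-index tables pooled over storage conditions."""
    tables = {}
    for pesticide, grp in dataset.groupby("pesticide", sort=False):
        parts = []
        for (t, h), series in grp.groupby(["temperature_C", "humidity_pct"]):
            series = series.sort_values("day")
            obs = series["concentration_mg_per_kg"].to_numpy()
            day_index = {d: i for i, d in enumerate(series["day"])}
            fc = forecasts[(forecasts["pesticide"] == pesticide)
                           & (forecasts["temperature_C"] == t)
                           & (forecasts["humidity_pct"] == h)]
            fdict = {}
            for day, sub in fc.groupby("origin_day"):
                if day in day_index:
                    fdict[day_index[day]] = sub.sort_values("step")[
                        "predicted_mg_per_kg"].to_numpy()
            part = build_quality_index(obs, fdict, n)
            part["temperature_C"] = t
            part["humidity_pct"] = h
            parts.append(part)
        tables[pesticide] = pd.concat(parts, ignore_index=True)
    return tables


def assess_stage(dataset: pd.DataFrame, forecasts: pd.DataFrame, cfg: dict,
                 out_dir: Path) -> pd.DataFrame:
    """Cluster per-pesticide quality indices and write the cluster and
    model-selection reports."""
    ass = cfg["assessment"]
    k_lo, k_hi = ass["k_range"]
    seed = rcio.stage_seed(cfg["seed"], "assess")
    tables = _quality_tables(dataset, forecasts, ass["n"])
    cluster_rows, selection_rows = [], []
    for pesticide, table in tables.items():
        points = table[["d", "dbar"]].to_numpy()
        evaluation, models = select_k(points, range(k_lo, k_hi + 1),
                                      seeds=ass["n_restarts"], base_seed=seed)
        sel = evaluation.table.copy()
        sel.insert(0, "pesticide", pesticide)
        selection_rows.append(sel)
        model = models[evaluation.chosen_k]
        levels = assign_quality_levels(model)
        for j in range(model.k):
            cluster_rows.append({
                "pesticide": pesticide, "cluster": j,
                "center_d": model.centers[j, 0],
                "center_dbar": model.centers[j, 1],
                "sample_size": int(model.sizes[j]),
                "quality_level": int(levels[j]),
            })
    clusters = pd.DataFrame(cluster_rows).sort_values(
        ["pesticide", "quality_level"]).reset_index(drop=True)
    selection = pd.concat(selection_rows, ignore_index=True)
    fmt = f"%.{rcio.CENTER_DECIMALS}f"
    clusters.to_csv(out_dir / "clusters.csv", index=False, float_format=fmt)
    selection.to_csv(out_dir / "cluster_selection.csv", index=False,
                     float_format=fmt)
    return clusters


def run_pipeline(cfg: dict, out_dir) -> Path:
    """Execute all stages, writing every intermediate artifact and a
    manifest.  Any stage error aborts with the stage name; artifacts
    written so far are preserved."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    stage = "simulate"
    try:
        dataset = simulate_stage(cfg)
        rcio.write_storage_csv(dataset, out_dir / "dataset.csv")
        limits = cfg["synthetic"]["limits"]
        flags = flag_over_limit(dataset, limits)
        stages[stage] = {
            "seed": rcio.stage_seed(cfg["seed"], stage),
            "rows": len(dataset),
            "split_sizes": dataset["split"].value_counts().to_dict(),
            "over_limit": int(flags.sum()),
        }

        stage = "train"
        model_cfg = cfg["model"]
        seed = rcio.stage_seed(cfg["seed"], stage)
        valid = AutoformerForecaster().get_params()
        est = AutoformerForecaster(
            **{k: v for k, v in model_cfg.items() if k in valid})
        est.set_params(random_state=seed)
        train_forecaster(est, dataset)
        pd.DataFrame({"epoch": range(1, len(est.loss_trace_) + 1),
                      "train_loss": est.loss_trace_}).to_csv(
            out_dir / "loss_trace.csv", index=False)
        stages[stage] = {"seed": seed, "epochs": len(est.loss_trace_),
                         "final_loss": est.loss_trace_[-1]}

        stage = "forecast"
        forecasts = forecast_all_days(est, dataset)
        forecasts.to_csv(out_dir / "forecasts.csv", index=False,
                         float_format=f"%.{rcio.CENTER_DECIMALS}f")
        stages[stage] = {"rows": len(forecasts)}

        stage = "assess"
        clusters = assess_stage(dataset, forecasts, cfg, out_dir)
        stages[stage] = {"seed": rcio.stage_seed(cfg["seed"], stage),
                         "rows": len(clusters)}

        stage = "compare"
        table = compare_models(
            dataset, model_names=("RNN", "LSTM", "Transformer", "Autoformer"),
            config=model_cfg, seed=rcio.stage_seed(cfg["seed"], stage))
        table.to_csv(out_dir / "metrics.csv")
        stages[stage] = {"seed": rcio.stage_seed(cfg["seed"], stage),
                         "models": list(table.reports)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    rcio.write_manifest(out_dir / "manifest.json", cfg, stages)
    return out_dir
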