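"""CSV readers/writers, configuration, seeds and run manifests.

Storage tables travel as UTF-8 CSV with a mandatory header::

    day,temperature_C,humidity_pct,pesticide,concentration_mg_per_kg[,split]

with '.' as the decimal separator.  Malformed rows are rejected
individually with their line numbers; structural problems (missing
columns, empty file) abort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import (COLUMNS, DEFAULT_CONDITIONS, DEFAULT_LIMITS,
                        KineticParams, StorageCondition, default_kinetic_params)

__all__ = [
    "read_storage_csv", "write_storage_csv", "load_config", "default_config",
    "stage_seed", "write_manifest", "METRIC_DECIMALS", "CENTER_DECIMALS",
]

logger = logging.getLogger(__name__)

METRIC_DECIMALS = 5   # error-metric tables
CENTER_DECIMALS = 8   # cluster-center tables


def read_storage_csv(path) -> pd.DataFrame:
    """Read a storage-record table, rejecting malformed rows.

    Rows with a non-numeric concentration (including localized decimal
    commas), a negative or non-integer day, or a missing pesticide name
    are dropped with their line numbers logged.  A missing column or an
    empty file raises.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing file")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    rows = []
    for i, row in raw.iterrows():
        line = i + 2  # header is line 1
        try:
            day = int(row["day"])
            if day < 0:
                raise ValueError("negative day")
            conc = float(row["concentration_mg_per_kg"])
            temp = float(row["temperature_C"])
            hum = float(row["humidity_pct"])
            pest = row["pesticide"].strip()
            if not pest:
                raise ValueError("missing pesticide name")
        except (ValueError, TypeError) as exc:
            logger.warning("%s line %d rejected: %s", path.name, line, exc)
            continue
        rec = {"day": day, "temperature_C": temp, "humidity_pct": hum,
               "pesticide": pest, "concentration_mg_per_kg": conc}
        if "split" in raw.columns:
            rec["split"] = row["split"]
        rows.append(rec)
    if not rows:
        raise ValueError(f"{path}: no valid records")
    return pd.DataFrame(rows)


def write_storage_csv(dataset: pd.DataFrame, path) -> None:
    cols = COLUMNS + (["split"] if "split" in dataset.columns else [])
    dataset.to_csv(path, index=False, columns=cols)


def default_config() -> dict:
    """Fully populated pipeline configuration with the study defaults."""
    return {
        "seed": 0,
        "synthetic": {
            "n_days": 90,
            "temperatures_C": [10.0, 25.0, 35.0],
            "humidities_pct": [54.0, 65.0, 75.0],
            "ratios": [0.7, 0.2, 0.1],
            "pesticides": {
                name: {
                    "initial_concentration": p.initial_concentration,
                    "base_rate": p.base_rate,
                    "temp_sensitivity": p.temp_sensitivity,
                    "humidity_sensitivity": p.humidity_sensitivity,
                    "reference_temperature": p.reference_temperature,
                    "reference_humidity": p.reference_humidity,
                    "noise_sd": p.noise_sd,
                } for name, p in default_kinetic_params().items()
            },
            "limits": dict(DEFAULT_LIMITS),
        },
        "model": {
            "context_length": 14, "label_length": 7, "horizon": 7,
            "model_width": 32, "n_heads": 2, "n_encoder_layers": 1,
            "n_decoder_layers": 1, "feedforward_width": 64,
            "decomp_kernel": 9, "autocorr_factor": 1.0, "dropout": 0.05,
            "epochs": 8, "batch_size": 64, "learning_rate": 5e-3,
        },
        "assessment": {"n": 7, "k_range": [2, 7], "n_restarts": 10},
    }


def load_config(path=None) -> dict:
    """YAML pipeline config merged over the defaults (section-wise)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def kinetic_params_from_config(cfg: dict) -> dict[str, KineticParams]:
    return {name: KineticParams(**vals)
            for name, vals in cfg["synthetic"]["pesticides"].items()}


def conditions_from_config(cfg: dict) -> list[StorageCondition]:
    return [StorageCondition(temperature=t, humidity=h)
            for t in cfg["synthetic"]["temperatures_C"]
            for h in cfg["synthetic"]["humidities_pct"]]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with a hash of
    the stage name, kept below 2**31 so every consumer accepts it."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(path, cfg: dict, stages: dict) -> None:
    """Record seeds, config hash, and per-stage row counts for
    reproducibility auditing."""
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.get("seed"),
        "stages": stages,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
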