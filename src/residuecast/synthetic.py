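"""Synthetic storage-monitoring data with first-order degradation kinetics.

Emulates daily silo monitoring of pesticide residues in stored wheat:
three pesticides (dimethoate, chlorpyrifos, chlorpyrifos-methyl)
followed over a 90-day storage period under a 3x3 factorial of storage
temperatures {10, 25, 35} degC and relative humidities {54, 65, 75} %.

Residues decay by first-order kinetics: concentration declines
exponentially at a rate that grows exponentially with temperature and
linearly with humidity, so warmer and damper storage degrades residues
faster.  Assay noise is multiplicative Gaussian.  Dimethoate and
chlorpyrifos-methyl are parameterised to degrade fast and to be
strongly temperature-sensitive; chlorpyrifos degrades slowly and
responds weakly to either factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StorageCondition",
    "KineticParams",
    "ResidueSeries",
    "PESTICIDES",
    "DEFAULT_CONDITIONS",
    "DEFAULT_LIMITS",
    "default_kinetic_params",
    "degradation_rate",
    "simulate_series",
    "build_dataset",
    "split_dataset",
    "flag_over_limit",
]

PESTICIDES = ("dimethoate", "chlorpyrifos", "chlorpyrifos-methyl")

#: Regulatory maximum residue limits in wheat, mg/kg.  The national
#: standard's list is ambiguous for the 0.05 entry; it is mapped to
#: dimethoate here (see docs/methods.md).
DEFAULT_LIMITS = {
    "dimethoate": 0.05,
    "chlorpyrifos": 0.5,
    "chlorpyrifos-methyl": 5.0,
}

COLUMNS = ["day", "temperature_C", "humidity_pct", "pesticide", "concentration_mg_per_kg"]


@dataclass(frozen=True)
class StorageCondition:
    """One silo climate: temperature in degC, relative humidity in %."""

    temperature: float
    humidity: float

    def __post_init__(self):
        if not -10.0 <= self.temperature <= 60.0:
            raise ValueError(f"temperature {self.temperature} outside [-10, 60] degC")
        if not 0.0 < self.humidity <= 100.0:
            raise ValueError(f"humidity {self.humidity} outside (0, 100] %")


DEFAULT_CONDITIONS = tuple(
    StorageCondition(temperature=t, humidity=h)
    for t in (10.0, 25.0, 35.0)
    for h in (54.0, 65.0, 75.0)
)


@dataclass(frozen=True)
class KineticParams:
    """First-order degradation kinetics for one pesticide.

    rate(T, H) = base_rate * exp(temp_sensitivity * (T - T_ref))
                           * (1 + humidity_sensitivity * (H - H_ref))

    ``noise_sd`` is the relative (multiplicative) assay noise.
    """

    initial_concentration: float
    base_rate: float
    temp_sensitivity: float = 0.0
    humidity_sensitivity: float = 0.0
    reference_temperature: float = 25.0
    reference_humidity: float = 65.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.initial_concentration <= 0:
            raise ValueError("initial_concentration must be > 0")
        for name in ("base_rate", "temp_sensitivity", "humidity_sensitivity"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.noise_sd < 0.5:
            raise ValueError(f"noise_sd must be in [0, 0.5), got {self.noise_sd}")


def default_kinetic_params() -> dict[str, KineticParams]:
    """Per-pesticide defaults.

    Initial concentrations sit near each compound's typical residue
    scale in wheat (mg/kg); dimethoate and chlorpyrifos-methyl get fast,
    temperature-sensitive kinetics while chlorpyrifos is slow and only
    weakly condition-dependent.
    """
    return {
        "dimethoate": KineticParams(
            initial_concentration=0.055, base_rate=0.020,
            temp_sensitivity=0.060, humidity_sensitivity=0.010, noise_sd=0.05),
        "chlorpyrifos": KineticParams(
            initial_concentration=0.35, base_rate=0.006,
            temp_sensitivity=0.015, humidity_sensitivity=0.004, noise_sd=0.05),
        "chlorpyrifos-methyl": KineticParams(
            initial_concentration=3.5, base_rate=0.025,
            temp_sensitivity=0.055, humidity_sensitivity=0.010, noise_sd=0.05),
    }


@dataclass(frozen=True)
class ResidueSeries:
    """One pesticide's daily concentration trajectory under one condition."""

    pesticide: str
    condition: StorageCondition
    days: np.ndarray = field(repr=False)
    concentrations: np.ndarray = field(repr=False)

    def __post_init__(self):
        days = np.asarray(self.days)
        conc = np.asarray(self.concentrations, dtype=np.float64)
        if days.shape != conc.shape or days.ndim != 1:
            raise ValueError("days and concentrations must be equal-length 1-D arrays")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(conc)) or np.any(conc < 0):
            raise ValueError("concentrations must be finite and >= 0")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "concentrations", conc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.days,
            "temperature_C": self.condition.temperature,
            "humidity_pct": self.condition.humidity,
            "pesticide": self.pesticide,
            "concentration_mg_per_kg": self.concentrations,
        })


def degradation_rate(params: KineticParams, condition: StorageCondition) -> float:
    """First-order decay rate (per day) at the given storage condition.

    Strictly increasing in temperature and humidity when the respective
    sensitivities are positive.  A humidity far below reference with a
    large sensitivity can drive the linear modifier negative; the rate
    is then clamped to 0 with a warning.
    """
    rate = (
        params.base_rate
        * np.exp(params.temp_sensitivity * (condition.temperature - params.reference_temperature))
        * (1.0 + params.humidity_sensitivity * (condition.humidity - params.reference_humidity))
    )
    if rate < 0:
        warnings.warn(
            f"degradation rate {rate:.4g} < 0 at T={condition.temperature}, "
            f"H={condition.humidity}; clamped to 0", stacklevel=2)
        return 0.0
    return float(rate)


def simulate_series(params: KineticParams, condition: StorageCondition,
                    n_days: int, seed: int,
                    pesticide: str = "dimethoate") -> ResidueSeries:
    """Simulate one noisy exponential-decay trajectory.

    concentration(t) = C0 * exp(-rate * t) * (1 + eps_t), with
    eps_t ~ Normal(0, noise_sd^2) i.i.d., clipped below at 0.
    Deterministic given ``seed``.
    """
    if n_days < 2:
        raise ValueError(f"n_days must be >= 2, got {n_days}")
    rate = degradation_rate(params, condition)
    days = np.arange(n_days)
    clean = params.initial_concentration * np.exp(-rate * days)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.noise_sd, size=n_days) if params.noise_sd > 0 else 0.0
    conc = np.clip(clean * (1.0 + noise), 0.0, None)
    return ResidueSeries(pesticide=pesticide, condition=condition,
                         days=days, concentrations=conc)


def build_dataset(pesticide_params: dict[str, KineticParams],
                  conditions: tuple[StorageCondition, ...] | list[StorageCondition],
                  n_days: int, seed: int) -> pd.DataFrame:
    """One simulated series per (pesticide x condition), as a flat table.

    The default configuration (3 pesticides x 9 conditions x 90 days)
    yields 2430 records.  Child seeds are spawned deterministically per
    series, so identical inputs give bit-identical tables.
    """
    if not pesticide_params or not len(conditions):
        raise ValueError("pesticide_params and conditions must be non-empty")
    conditions = list(conditions)
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate storage conditions")
    frames = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pesticide_params) * len(conditions))
    i = 0
    for pesticide, params in pesticide_params.items():
        for cond in conditions:
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            series = simulate_series(params, cond, n_days, child_seed)
            frame = series.to_frame()
            frame["pesticide"] = pesticide
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)[COLUMNS]


def _series_groups(dataset: pd.DataFrame) -> list[np.ndarray]:
    """Row-index groups, one per (pesticide, condition) series, each
    sorted chronologically."""
    keys = ["pesticide", "temperature_C", "humidity_pct"]
    groups = []
    for _, grp in dataset.groupby(keys, sort=False):
        groups.append(grp.sort_values("day", kind="stable").index.to_numpy())
    return groups


_FLOOR_EPS = 1e-9  # absorb float representation error before flooring


def _apportion(targets: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items over fractional
    ``targets`` (floor everyone, hand out the shortfall to the largest
    remainders, earlier entries first on ties; withdraw from the
    smallest remainders if the floors overshoot)."""
    base = np.floor(targets + _FLOOR_EPS).astype(int)
    frac = targets - np.floor(targets + _FLOOR_EPS)
    shortfall = total - base.sum()
    if shortfall > 0:
        order = np.lexsort((np.arange(len(frac)), -frac))
        for j in order[:shortfall]:
            base[j] += 1
    elif shortfall < 0:
        order = np.lexsort((np.arange(len(frac)), frac))
        for j in order:
            if shortfall == 0:
                break
            if base[j] > 0:
                base[j] -= 1
                shortfall += 1
    return base


def split_dataset(dataset: pd.DataFrame,
                  ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)) -> pd.DataFrame:
    """Tag each record train / test / validation.

    With N total records the global sizes are ``train = floor(r_train*N)``,
    ``test = round(r_test*N)`` and ``validation = N - train - test``
    (so 2655 records at 7:2:1 split as 1858 / 531 / 266).  Within each
    (pesticide, condition) series the split is chronological — the
    earliest records train, then test, then validation — so no future
    value leaks into training; series quotas are set by largest-remainder
    apportionment so the global sizes hold exactly.
    """
    r = np.asarray(ratios, dtype=np.float64)
    if np.any(r <= 0) or not np.isclose(r.sum(), 1.0):
        raise ValueError(f"ratios must be positive and sum to 1, got {ratios}")
    n = len(dataset)
    n_train = int(np.floor(r[0] * n + _FLOOR_EPS))
    n_test = int(round(r[1] * n))
    n_val = n - n_train - n_test
    if min(n_train, n_test, n_val) < 1:
        raise ValueError(
            f"{n} records cannot form three non-empty splits at ratios {ratios}")

    groups = _series_groups(dataset)
    sizes = np.array([len(g) for g in groups])
    train_quota = _apportion(r[0] * sizes, n_train)
    test_quota = _apportion(r[1] * sizes, n_test)
    # guard tiny series: test quota cannot exceed what train left behind
    for j in range(len(groups)):
        over = train_quota[j] + test_quota[j] - sizes[j]
        if over > 0:
            test_quota[j] -= over
            room = sizes - train_quota - test_quota
            for k in np.argsort(-room):
                if over == 0:
                    break
                give = min(over, room[k])
                test_quota[k] += give
                over -= give

    assignment = pd.Series(index=dataset.index, dtype=object)
    for g, tr, te in zip(groups, train_quota, test_quota):
        assignment.loc[g[:tr]] = "train"
        assignment.loc[g[tr:tr + te]] = "test"
        assignment.loc[g[tr + te:]] = "validation"
    out = dataset.copy()
    out["split"] = assignment
    return out


def flag_over_limit(dataset: pd.DataFrame,
                    limits: dict[str, float] | None = None) -> pd.Series:
    """Boolean per-record flag: concentration strictly above the
    pesticide's maximum residue limit (a record exactly at the limit is
    compliant)."""
    limits = DEFAULT_LIMITS if limits is None else limits
    if any(v <= 0 for v in limits.values()):
        raise ValueError("limits must be positive")
    missing = set(dataset["pesticide"]) - set(limits)
    if missing:
        raise KeyError(f"no residue limit for pesticide(s): {sorted(missing)}")
    limit_col = dataset["pesticide"].map(limits)
    return dataset["concentration_mg_per_kg"] > limit_col
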