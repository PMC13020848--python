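"""Trainable surrogate estimators of the virtual greenhouse.

Three surrogates stand in for the dynamics oracle once trained on its tables:

* a feed-forward **climate estimator** (two ReLU hidden layers) mapping
  outside weather + control setpoints to the hourly indoor climate,
* a **crop estimator** (Conv1D + LSTM) mapping a week of daily climate
  aggregates to the weekly crop increments,
* a **resource estimator** (Conv1D + LSTM) mapping a day of hourly climate
  to the five daily resource-consumption totals.

All models train and report mean absolute error on min–max-normalized
features, with seeded splits, and bind inputs by column name.  A
random-forest importance ranking provides optional feature selection.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from . import _nn
from .oracle import (
    CLIMATE_COLUMNS,
    DAYS_PER_WEEK,
    HOURS_PER_DAY,
    RESOURCE_COLUMNS,
    SETPOINT_COLUMNS,
)
from .weather import WEATHER_COLUMNS

EPISODE_DAYS = 23 * 7  # horizon used to normalize the "days" feature


class DegenerateFeatureError(ValueError):
    """A feature is constant and cannot be min–max scaled."""


class FeatureSchemaError(KeyError):
    """A required feature or target column is absent."""


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

@dataclass
class NormalizationSpec:
    """Named-column min–max scaling to [0, 1], optionally clamped."""

    columns: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    clamp: bool = False

    def normalize(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise FeatureSchemaError(f"missing columns: {missing}")
        x = table[self.columns].to_numpy(dtype=float)
        z = (x - self.mins) / (self.maxs - self.mins)
        if self.clamp:
            z = np.clip(z, 0.0, 1.0)
        return pd.DataFrame(z, columns=self.columns, index=table.index)

    def denormalize(self, table: pd.DataFrame) -> pd.DataFrame:
        z = table[self.columns].to_numpy(dtype=float)
        x = z * (self.maxs - self.mins) + self.mins
        return pd.DataFrame(x, columns=self.columns, index=table.index)

    def to_dict(self) -> dict:
        return {"columns": self.columns, "mins": self.mins.tolist(),
                "maxs": self.maxs.tolist(), "clamp": self.clamp}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(d["columns"], np.asarray(d["mins"], dtype=float),
                   np.asarray(d["maxs"], dtype=float), d["clamp"])


def fit_normalizer(table: pd.DataFrame, columns: list[str] | None = None,
                   clamp: bool = False) -> NormalizationSpec:
    """Fit per-column min–max scaling; constant columns are rejected."""
    columns = list(columns) if columns is not None else list(table.columns)
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise FeatureSchemaError(f"missing columns: {missing}")
    x = table[columns].to_numpy(dtype=float)
    mins, maxs = x.min(axis=0), x.max(axis=0)
    degenerate = [c for c, lo, hi in zip(columns, mins, maxs) if hi <= lo]
    if degenerate:
        raise DegenerateFeatureError(
            f"constant features cannot be scaled: {degenerate}")
    return NormalizationSpec(columns, mins, maxs, clamp)


# --------------------------------------------------------------------------
# random-forest feature ranking
# --------------------------------------------------------------------------

@dataclass
class FeatureRanking:
    """Features ordered by descending importance; scores sum to one."""

    features: list[str]
    importances: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(-self.importances, kind="stable")
        self.features = [self.features[i] for i in order]
        self.importances = self.importances[order]
        total = self.importances.sum()
        if total > 0:
            self.importances = self.importances / total

    def __len__(self) -> int:
        return len(self.features)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.features,
                             "importance": self.importances})


def rank_features(table: pd.DataFrame, target_columns: list[str],
                  n_trees: int = 200, seed: int = 0,
                  max_rows: int = 20000) -> FeatureRanking:
    """Rank predictor columns by random-forest importance.

    One forest is fitted per target and the normalized importances are
    averaged over targets, so multi-output problems weight each target
    equally.
    """
    missing = [c for c in target_columns if c not in table.columns]
    if missing:
        raise FeatureSchemaError(f"missing target columns: {missing}")
    if len(table) < 50:
        raise ValueError("feature ranking needs at least 50 rows")
    features = [c for c in table.columns if c not in target_columns]
    sub = table
    if len(table) > max_rows:
        sub = table.sample(max_rows, random_state=seed)
    x = sub[features].to_numpy(dtype=float)
    scores = np.zeros(len(features))
    for target in target_columns:
        forest = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1,
            max_depth=12, min_samples_leaf=2)
        forest.fit(x, sub[target].to_numpy(dtype=float))
        scores += forest.feature_importances_
    return FeatureRanking(features, scores / len(target_columns))


def select_top_features(ranking: FeatureRanking, k: int | None = None,
                        threshold: float | None = None) -> list[str]:
    """Top-k features, or the smallest prefix reaching a cumulative share."""
    if (k is None) == (threshold is None):
        raise ValueError("pass exactly one of k or threshold")
    if k is not None:
        if k <= 0:
            raise ValueError(f"k must be positive, got {k}")
        if k > len(ranking):
            raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
        return ranking.features[:k]
    cum = np.cumsum(ranking.importances)
    n = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return ranking.features[:min(n, len(ranking))]


# --------------------------------------------------------------------------
# training tables from oracle datasets
# --------------------------------------------------------------------------

def build_climate_table(dataset: dict) -> pd.DataFrame:
    """Hourly rows of weather + setpoints (features) and climate (targets)."""
    climate = dataset["climate"]
    weather_h = dataset["weather"].resample("1h").mean()
    weather_h = weather_h.loc[climate.index]
    n_hours = len(climate)
    week_of_hour = np.arange(n_hours) // (DAYS_PER_WEEK * HOURS_PER_DAY)
    sp = dataset["setpoints"].iloc[week_of_hour].reset_index(drop=True)
    sp.index = climate.index
    days = pd.Series(np.arange(n_hours) / HOURS_PER_DAY / EPISODE_DAYS,
                     index=climate.index, name="days")
    return pd.concat([weather_h, sp, days, climate[CLIMATE_COLUMNS]], axis=1)


CLIMATE_FEATURES = WEATHER_COLUMNS + SETPOINT_COLUMNS + ["days"]

#: Daily aggregate features driving the weekly crop model.
CROP_SEQ_FEATURES = [
    "Tair", "Tot_PAR", "CO2air", "Rhair", "HumDef", "Cum_irr",
    "EC_drain_PC", "pH_drain_PC", "t_heat_sp", "CO2_sp",
    "water_sup_int_sp_min", "days",
]

#: Hourly features driving the daily resource model.
RESOURCE_SEQ_FEATURES = [
    "Tair", "CO2air", "Rhair", "HumDef", "Tot_PAR", "Tot_PAR_Lamps",
    "AssimLight", "BlackScr", "EnScr", "CO2_dos", "Cum_irr",
    "EC_drain_PC", "pH_drain_PC", "_Tout", "_Iglob",
    "t_heat_sp", "CO2_sp", "water_sup_int_sp_min", "days",
]

CROP_TARGETS = ["Stem_elong", "Stem_thick", "Truss_inc"]


def build_crop_sequences(dataset: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily-aggregate table and weekly crop-increment targets.

    Returns ``(daily, weekly)`` where ``daily`` has one row per day (the
    sequence elements) and ``weekly`` one row per week with the increment
    targets (``Truss_inc`` is the week-on-week Cum_truss difference).
    """
    climate = dataset["climate"]
    n_days = len(climate) // HOURS_PER_DAY
    day_of_hour = np.arange(len(climate)) // HOURS_PER_DAY
    daily = climate.groupby(day_of_hour).mean()
    daily["Cum_irr"] = climate["Cum_irr"].groupby(day_of_hour).max()
    week_of_day = np.arange(n_days) // DAYS_PER_WEEK
    sp = dataset["setpoints"].iloc[week_of_day].reset_index(drop=True)
    daily = pd.concat([daily.reset_index(drop=True), sp], axis=1)
    daily["days"] = np.arange(n_days) / EPISODE_DAYS
    crop = dataset["crop"].copy()
    crop["Truss_inc"] = crop["Cum_truss"].diff().fillna(crop["Cum_truss"])
    return daily, crop[CROP_TARGETS]


def build_resource_sequences(dataset: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly feature table and daily resource targets."""
    climate = dataset["climate"].copy()
    n_hours = len(climate)
    week_of_hour = np.arange(n_hours) // (DAYS_PER_WEEK * HOURS_PER_DAY)
    sp = dataset["setpoints"].iloc[week_of_hour].reset_index(drop=True)
    sp.index = climate.index
    hourly = pd.concat([climate, sp[["t_heat_sp", "CO2_sp",
                                     "water_sup_int_sp_min"]]], axis=1)
    hourly["days"] = np.arange(n_hours) / HOURS_PER_DAY / EPISODE_DAYS
    return hourly, dataset["resources"][RESOURCE_COLUMNS]


# --------------------------------------------------------------------------
# estimator specs and wrappers
# --------------------------------------------------------------------------

@dataclass
class ClimateEstimatorSpec:
    """Feed-forward climate-estimator configuration (two ReLU layers)."""

    features: list[str] = field(default_factory=lambda: list(CLIMATE_FEATURES))
    targets: list[str] = field(default_factory=lambda: list(CLIMATE_COLUMNS))
    hidden: tuple[int, int] = (256, 128)
    epochs: int = 40
    batch_size: int = 128
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.features or not self.targets:
            raise ValueError("feature and target lists must be non-empty")
        overlap = set(self.features) & set(self.targets)
        if overlap:
            raise ValueError(f"features and targets overlap: {sorted(overlap)}")
        if any(w < 1 for w in self.hidden):
            raise ValueError("hidden widths must be >= 1")


@dataclass
class SequenceEstimatorSpec:
    """Conv1D+LSTM sequence-estimator configuration."""

    features: list[str]
    targets: list[str]
    window: int
    conv_channels: int = 16
    kernel: int = 3
    hidden: int = 32
    epochs: int = 120
    batch_size: int = 32
    learning_rate: float = 3e-3
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not self.features or not self.targets:
            raise ValueError("feature and target lists must be non-empty")


class ClimateEstimator:
    """Trained feed-forward surrogate for the hourly indoor climate."""

    def __init__(self, spec: ClimateEstimatorSpec, norm_x: NormalizationSpec,
                 norm_y: NormalizationSpec, model: _nn.MLP):
        self.spec, self.norm_x, self.norm_y, self.model = (
            spec, norm_x, norm_y, model)

    def predict_normalized(self, features: pd.DataFrame) -> pd.DataFrame:
        x = self.norm_x.normalize(features).to_numpy()
        z = np.clip(self.model.predict(x), 0.0, 1.0)
        return pd.DataFrame(z, columns=self.spec.targets,
                            index=features.index)

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        return self.norm_y.denormalize(self.predict_normalized(features))

    @property
    def n_parameters(self) -> int:
        return self.model.n_parameters


class SequenceEstimator:
    """Trained Conv1D+LSTM surrogate over fixed-length windows."""

    def __init__(self, spec: SequenceEstimatorSpec, norm_x: NormalizationSpec,
                 norm_y: NormalizationSpec, model: _nn.SequenceNet):
        self.spec, self.norm_x, self.norm_y, self.model = (
            spec, norm_x, norm_y, model)

    def _window(self, rows: pd.DataFrame) -> np.ndarray:
        if len(rows) != self.spec.window:
            raise ValueError(
                f"expected {self.spec.window} rows, got {len(rows)}")
        return self.norm_x.normalize(rows).to_numpy()[None, :, :]

    def predict_normalized(self, rows: pd.DataFrame) -> np.ndarray:
        return np.clip(self.model.predict(self._window(rows))[0], 0.0, 1.0)

    def predict(self, rows: pd.DataFrame) -> pd.Series:
        z = pd.DataFrame([self.predict_normalized(rows)],
                         columns=self.spec.targets)
        return self.norm_y.denormalize(z).iloc[0]

    @property
    def n_parameters(self) -> int:
        return self.model.n_parameters


def _split(n: int, val_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    return order[n_val:], order[:n_val]


def train_climate_estimator(table: pd.DataFrame,
                            spec: ClimateEstimatorSpec
                            ) -> tuple[ClimateEstimator, float]:
    """Train the climate surrogate; returns (estimator, held-out MAE).

    The MAE is reported in normalized units on a seeded held-out split.
    """
    for col in spec.features + spec.targets:
        if col not in table.columns:
            raise FeatureSchemaError(f"missing column: {col}")
    norm_x = fit_normalizer(table, spec.features, clamp=True)
    norm_y = fit_normalizer(table, spec.targets, clamp=True)
    x = norm_x.normalize(table).to_numpy()
    y = norm_y.normalize(table).to_numpy()
    tr, va = _split(len(x), spec.val_fraction, spec.seed)
    model = _nn.MLP([len(spec.features), *spec.hidden, len(spec.targets)],
                    seed=spec.seed)
    _nn.fit(model, x[tr], y[tr], epochs=spec.epochs,
            batch_size=spec.batch_size, lr=spec.learning_rate,
            seed=spec.seed)
    val_mae = _nn.mae(np.clip(model.predict(x[va]), 0.0, 1.0), y[va])
    return ClimateEstimator(spec, norm_x, norm_y, model), val_mae


def _stack_windows(rows: pd.DataFrame, targets: pd.DataFrame, window: int,
                   norm_x: NormalizationSpec, norm_y: NormalizationSpec):
    """Group a flat row table into (n_targets, window, features) windows."""
    n_seq = len(targets)
    if len(rows) < n_seq * window:
        raise ValueError(
            f"history of {len(rows)} rows shorter than "
            f"{n_seq} windows of {window}")
    x = norm_x.normalize(rows).to_numpy()[:n_seq * window]
    y = norm_y.normalize(targets).to_numpy()
    return x.reshape(n_seq, window, -1), y


def train_sequence_estimator(rows: pd.DataFrame, targets: pd.DataFrame,
                             spec: SequenceEstimatorSpec
                             ) -> tuple[SequenceEstimator, float]:
    """Train a Conv1D+LSTM surrogate on consecutive fixed-length windows.

    ``rows`` holds the sequence elements in time order (``window`` rows per
    target); ``targets`` one row per window.
    """
    for col in spec.features:
        if col not in rows.columns:
            raise FeatureSchemaError(f"missing feature column: {col}")
    norm_x = fit_normalizer(rows, spec.features, clamp=True)
    norm_y = fit_normalizer(targets, spec.targets, clamp=True)
    x, y = _stack_windows(rows, targets, spec.window, norm_x, norm_y)
    tr, va = _split(len(x), spec.val_fraction, spec.seed)
    model = _nn.SequenceNet(
        n_features=len(spec.features), n_out=len(spec.targets),
        conv_channels=spec.conv_channels, kernel=spec.kernel,
        hidden=spec.hidden, seed=spec.seed)
    _nn.fit(model, x[tr], y[tr], epochs=spec.epochs,
            batch_size=spec.batch_size, lr=spec.learning_rate,
            seed=spec.seed)
    val_mae = _nn.mae(np.clip(model.predict(x[va]), 0.0, 1.0), y[va])
    return SequenceEstimator(spec, norm_x, norm_y, model), val_mae


# --------------------------------------------------------------------------
# persistence: npz weights + JSON sidecar
# --------------------------------------------------------------------------

def save_estimator(est, path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **est.model.params)
    kind = "climate" if isinstance(est, ClimateEstimator) else "sequence"
    sidecar = {
        "kind": kind,
        "spec": dataclasses.asdict(est.spec),
        "norm_x": est.norm_x.to_dict(),
        "norm_y": est.norm_y.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_estimator(path):
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    weights = dict(np.load(path.with_suffix(".npz")))
    norm_x = NormalizationSpec.from_dict(sidecar["norm_x"])
    norm_y = NormalizationSpec.from_dict(sidecar["norm_y"])
    sd = sidecar["spec"]
    if sidecar["kind"] == "climate":
        sd["hidden"] = tuple(sd["hidden"])
        spec = ClimateEstimatorSpec(**sd)
        model = _nn.MLP([len(spec.features), *spec.hidden,
                         len(spec.targets)], seed=spec.seed)
        model.params.update(weights)
        return ClimateEstimator(spec, norm_x, norm_y, model)
    spec = SequenceEstimatorSpec(**sd)
    model = _nn.SequenceNet(
        n_features=len(spec.features), n_out=len(spec.targets),
        conv_channels=spec.conv_channels, kernel=spec.kernel,
        hidden=spec.hidden, seed=spec.seed)
    model.params.update(weights)
    return SequenceEstimator(spec, norm_x, norm_y, model)
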