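"""Weekly-cycle episodic control environment for the virtual greenhouse.

The agent proposes eight continuous setpoints in [0, 1] once per simulated
week; each step advances 2016 five-minute timesteps (7 days), internally
producing 168 hourly climate states, 7 daily resource totals aggregated to a
weekly draw, and one weekly crop update, all over the same weather window.
Episodes run at most 23 weeks (one tomato production cycle) and may end early
on resource overuse or sustained crop-quality failure.

The environment follows the standard episodic contract —
``reset(seed) -> (observation, info)`` and
``step(action) -> (observation, reward, terminated, truncated, info)`` —
with a dictionary observation of normalized components.  Two interchangeable
backends drive the dynamics: the parametric oracle, or the trained surrogate
estimators.
"""

from __future__ import annotations

import json
import logging
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rewards
from .estimators import (
    CROP_SEQ_FEATURES,
    EPISODE_DAYS,
    RESOURCE_SEQ_FEATURES,
)
from .oracle import (
    DAYS_PER_WEEK,
    HOURS_PER_DAY,
    TIMESTEPS_PER_WEEK,
    OracleParams,
    SetpointVector,
    simulate_climate,
    simulate_crop,
    simulate_resources,
    weekly_aggregates,
)
from .weather import WEATHER_COLUMNS, WeatherGenConfig, generate_weather

logger = logging.getLogger(__name__)

#: The eight agent-controlled setpoints, in action-vector order.
ACTION_COMPONENTS = [
    "CO2_sp", "scr_enrg_sp", "scr_blck_sp", "t_heat_sp", "t_vent_sp",
    "water_sup_int_sp_min", "pH_drain_sp", "int_white_sp",
]

#: Plausible physical ranges used to normalize climate observations.
OBS_CLIMATE_RANGES = {
    "Tair": (5.0, 40.0), "Rhair": (0.0, 100.0), "CO2air": (300.0, 1500.0),
    "HumDef": (0.0, 10.0), "VentLee": (0.0, 100.0), "Ventwind": (0.0, 100.0),
    "AssimLight": (0.0, 100.0), "EnScr": (0.0, 100.0),
    "BlackScr": (0.0, 100.0), "PipeLow": (0.0, 60.0), "PipeGrow": (0.0, 60.0),
    "CO2_dos": (0.0, 60.0), "Tot_PAR": (0.0, 1500.0),
    "Tot_PAR_Lamps": (0.0, 400.0), "EC_drain_PC": (0.0, 6.0),
    "pH_drain_PC": (4.0, 8.0), "Water_sup": (0.0, 120.0),
    "Cum_irr": (0.0, 10.0),
}

WEATHER_SUMMARY_RANGES = {
    "Tout": (-10.0, 40.0), "Rhout": (0.0, 100.0), "Iglob": (0.0, 1000.0),
    "Windsp": (0.0, 20.0), "Winddir": (0.0, 128.0), "RadSum": (0.0, 3000.0),
    "PARout": (0.0, 2100.0), "Pyrogeo": (-100.0, 50.0), "Rain": (0.0, 1.0),
    "AbsHumOut": (0.0, 30.0),
}


class EpisodeFinishedError(RuntimeError):
    """step() was called after the episode terminated or truncated."""


@dataclass
class ActionScaling:
    """Affine map from agent actions in [0, 1] to physical setpoints.

    The two screen components are binary in the challenge layout (fully open
    or fully closed) and threshold at 0.5 instead of scaling affinely.
    """

    ranges: dict = field(default_factory=lambda: {
        "CO2_sp": (400.0, 1000.0),
        "scr_enrg_sp": (0.0, 100.0),
        "scr_blck_sp": (0.0, 100.0),
        "t_heat_sp": (14.0, 26.0),
        "t_vent_sp": (16.0, 30.0),
        "water_sup_int_sp_min": (30.0, 360.0),
        "pH_drain_sp": (5.0, 6.5),
        "int_white_sp": (0.0, 1000.0),
    })
    binary: tuple = ("scr_enrg_sp", "scr_blck_sp")

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"{name}: min must be < max, got ({lo},{hi})")

    def scale(self, action) -> dict[str, float]:
        action = np.asarray(action, dtype=float)
        if action.shape != (len(ACTION_COMPONENTS),):
            raise ValueError(
                f"action must have shape ({len(ACTION_COMPONENTS)},), "
                f"got {action.shape}")
        out = {}
        for a, name in zip(action, ACTION_COMPONENTS):
            lo, hi = self.ranges[name]
            if name in self.binary:
                out[name] = hi if a >= 0.5 else lo
            else:
                out[name] = lo + a * (hi - lo)
        return out

    def inverse_scale(self, setpoints: dict[str, float]) -> np.ndarray:
        """Inverse of :meth:`scale` for the continuous components;
        binary components map to {0, 1}."""
        out = np.empty(len(ACTION_COMPONENTS))
        for i, name in enumerate(ACTION_COMPONENTS):
            lo, hi = self.ranges[name]
            v = setpoints[name]
            if name in self.binary:
                out[i] = 1.0 if v >= (lo + hi) / 2.0 else 0.0
            else:
                out[i] = (v - lo) / (hi - lo)
        return out


def scale_action(action, scaling: ActionScaling,
                 base: SetpointVector | None = None) -> SetpointVector:
    """Merge the scaled 8-component action into a full setpoint vector.

    Uncontrolled setpoints keep the values of ``base`` (per-episode
    constants).
    """
    base = base or SetpointVector()
    return base.replace(**scaling.scale(action))


@dataclass
class EstimatorBundle:
    """The three trained surrogates backing the estimator backend."""

    climate: object
    crop: object
    resources: object


class GreenhouseEnv:
    """Episodic weekly-setpoint control of the virtual greenhouse.

    Parameters
    ----------
    reward_config
        Coefficients/thresholds of the multi-objective reward.
    oracle_params
        Dynamics parameters (used by the oracle backend, and by the
        estimator backend only for the weather).
    weather_mode
        ``"stochastic"`` regenerates a fresh weather realization each
        episode; ``"historical"`` replays the same seeded season.
    backend
        ``"oracle"`` for the parametric dynamics, ``"estimators"`` for the
        trained surrogates (requires ``estimator_bundle``).
    """

    metadata = {"render_modes": []}

    def __init__(self, reward_config: rewards.RewardConfig | None = None,
                 oracle_params: OracleParams | None = None,
                 weather_mode: str = "stochastic",
                 backend: str = "oracle",
                 estimator_bundle: EstimatorBundle | None = None,
                 weather_config: WeatherGenConfig | None = None,
                 base_setpoints: SetpointVector | None = None,
                 action_scaling: ActionScaling | None = None,
                 log_path=None):
        if weather_mode not in ("historical", "stochastic"):
            raise ValueError(f"unknown weather_mode: {weather_mode!r}")
        if backend not in ("oracle", "estimators"):
            raise ValueError(f"unknown backend: {backend!r}")
        if backend == "estimators" and estimator_bundle is None:
            raise ValueError("estimator backend requires an EstimatorBundle")
        self.reward_config = reward_config or rewards.RewardConfig()
        self.oracle_params = oracle_params or OracleParams()
        self.weather_mode = weather_mode
        self.backend = backend
        self.bundle = estimator_bundle
        self.weather_config = weather_config or WeatherGenConfig()
        self.base_setpoints = base_setpoints or SetpointVector()
        self.scaling = action_scaling or ActionScaling()
        self.log_path = log_path
        self._np_random = np.random.default_rng(0)
        self._done = True
        self._weather = None

    # -- episode control ---------------------------------------------------

    def reset(self, seed: int | None = None):
        if seed is not None:
            self._np_random = np.random.default_rng(seed)
        horizon_days = self.reward_config.max_steps * DAYS_PER_WEEK
        if self.weather_mode == "stochastic":
            wseed = int(self._np_random.integers(2 ** 31))
        else:
            wseed = self.weather_config.seed
        cfg = self.weather_config.replace(n_days=horizon_days, seed=wseed)
        self._weather = generate_weather(cfg)
        self._hourly_weather = self._weather.resample("1h").mean()
        n_weeks = self.reward_config.max_steps
        means = (self._weather[WEATHER_COLUMNS].to_numpy()
                 .reshape(n_weeks, TIMESTEPS_PER_WEEK, -1).mean(axis=1))
        lo = np.array([WEATHER_SUMMARY_RANGES[c][0] for c in WEATHER_COLUMNS])
        hi = np.array([WEATHER_SUMMARY_RANGES[c][1] for c in WEATHER_COLUMNS])
        radsum_week = (self._weather["RadSum"].iloc[287::288].to_numpy()
                       .reshape(n_weeks, DAYS_PER_WEEK).sum(axis=1))
        self._week_summaries = np.clip(np.column_stack([
            (means - lo) / (hi - lo),
            radsum_week / (7.0 * WEATHER_SUMMARY_RANGES["RadSum"][1]),
        ]), 0.0, 1.0)
        self._sim_rng = np.random.default_rng(
            int(self._np_random.integers(2 ** 31)))
        self._week = 0
        self._done = False
        self._prev_action = np.full(len(ACTION_COMPONENTS), 0.5)
        self._cum_resources = np.zeros(5)
        self._cum_truss = 0.0
        self._low_quality_streak = 0
        self._init_tair = None
        self._init_co2 = None
        self._last_climate_obs = np.zeros(len(OBS_CLIMATE_RANGES))
        self._last_crop_obs = np.zeros(3)
        self._last_resource_obs = np.zeros(5)
        return self._observation(), {"week": 0}

    def _observation(self) -> dict:
        week = min(self._week, self.reward_config.max_steps - 1)
        return {
            "climate": np.clip(self._last_climate_obs, 0.0, 1.0),
            "crop": np.clip(self._last_crop_obs, 0.0, 1.0),
            "resources": np.clip(self._last_resource_obs, 0.0, 1.0),
            "weather": self._week_summaries[week],
            "week_index": self._week,
        }

    # -- one week of dynamics ---------------------------------------------

    def _simulate_week(self, setpoints: SetpointVector, weather_slice,
                       hourly_slice):
        """Return (climate_hourly, resources_daily, crop_increments)."""
        if self.backend == "oracle":
            climate = simulate_climate(
                weather_slice, setpoints, self.oracle_params,
                rng=self._sim_rng, init_tair=self._init_tair,
                init_co2=self._init_co2, hourly=hourly_slice)
            resources = simulate_resources(climate, setpoints,
                                           self.oracle_params)
            agg = weekly_aggregates(climate, resources, self.oracle_params)
            crop = simulate_crop(agg, self.oracle_params, rng=self._sim_rng)
            self._init_tair = float(climate["Tair"].iloc[-1])
            self._init_co2 = float(climate["CO2air"].iloc[-1])
            inc = (float(crop["Stem_elong"].iloc[0]),
                   float(crop["Stem_thick"].iloc[0]),
                   float(crop["Cum_truss"].iloc[0]))
            return climate, resources, inc
        return self._simulate_week_estimators(setpoints, hourly_slice)

    def _simulate_week_estimators(self, setpoints: SetpointVector,
                                  hourly_weather):
        n_hours = len(hourly_weather)
        sp_row = setpoints.as_series()
        features = hourly_weather.copy()
        for name, value in sp_row.items():
            features[name] = value
        day0 = self._week * DAYS_PER_WEEK
        features["days"] = (day0 + np.arange(n_hours) / HOURS_PER_DAY
                            ) / EPISODE_DAYS
        climate = self.bundle.climate.predict(features)

        res_features = climate.copy()
        for name in ("t_heat_sp", "CO2_sp", "water_sup_int_sp_min"):
            res_features[name] = sp_row[name]
        res_features["days"] = features["days"].to_numpy()
        for col in self.bundle.resources.spec.features:
            if col not in res_features.columns:
                res_features[col] = hourly_weather.get(
                    col.lstrip("_"), pd.Series(0.0, index=climate.index))
        rows = []
        for d in range(DAYS_PER_WEEK):
            day = res_features.iloc[d * HOURS_PER_DAY:(d + 1) * HOURS_PER_DAY]
            rows.append(self.bundle.resources.predict(day))
        resources = pd.DataFrame(rows).reset_index(drop=True)

        day_of_hour = np.arange(n_hours) // HOURS_PER_DAY
        daily = climate.groupby(day_of_hour).mean()
        daily["Cum_irr"] = climate["Cum_irr"].groupby(day_of_hour).max()
        for name in ("t_heat_sp", "CO2_sp", "water_sup_int_sp_min"):
            daily[name] = sp_row[name]
        daily["days"] = (day0 + np.arange(DAYS_PER_WEEK)) / EPISODE_DAYS
        crop_pred = self.bundle.crop.predict(daily[
            self.bundle.crop.spec.features])
        inc = (float(crop_pred["Stem_elong"]),
               float(crop_pred["Stem_thick"]),
               float(crop_pred["Truss_inc"]))
        return climate, resources, inc

    def step(self, action):
        if self._done:
            raise EpisodeFinishedError(
                "episode finished; call reset() before stepping again")
        action = np.asarray(action, dtype=float)
        if action.shape != (len(ACTION_COMPONENTS),):
            raise ValueError(f"action must be an 8-vector, got {action.shape}")
        if (action < 0.0).any() or (action > 1.0).any():
            logger.warning("action outside [0, 1] clipped: %s", action)
            action = np.clip(action, 0.0, 1.0)

        setpoints = scale_action(action, self.scaling, self.base_setpoints)
        sl = self._weather.iloc[self._week * TIMESTEPS_PER_WEEK:
                                (self._week + 1) * TIMESTEPS_PER_WEEK]
        hourly_sl = self._hourly_weather.iloc[
            self._week * DAYS_PER_WEEK * HOURS_PER_DAY:
            (self._week + 1) * DAYS_PER_WEEK * HOURS_PER_DAY]
        climate, resources, inc = self._simulate_week(setpoints, sl,
                                                      hourly_sl)

        weekly_res = resources.sum(axis=0)
        res_tuple = (float(weekly_res["Heat_cons"]),
                     float(weekly_res["CO2_cons"]),
                     float(weekly_res["ElecHigh"]),
                     float(weekly_res["ElecLow"]),
                     float(weekly_res["Irr"]))
        cfg = self.reward_config
        thresholds = cfg.effective_overuse_thresholds()
        usage = {"heat": res_tuple[0], "co2": res_tuple[1],
                 "electricity": res_tuple[2] + res_tuple[3],
                 "irrigation": res_tuple[4]}
        overuse_flags = {k: usage[k] > thresholds[k] for k in thresholds}

        breakdown = rewards.total_reward(
            inc, res_tuple, self._prev_action, action, cfg,
            res_overuse=any(overuse_flags.values()))

        self._week += 1
        crop_norm = rewards.normalized_crop(inc, cfg)
        terminated, truncated, self._low_quality_streak = (
            rewards.check_termination(self._week, crop_norm,
                                      breakdown.terminate, cfg,
                                      self._low_quality_streak))
        self._done = terminated or truncated

        self._cum_resources = self._cum_resources + np.asarray(res_tuple)
        self._cum_truss += inc[2]
        last_climate = climate.iloc[-1]
        self._last_climate_obs = np.array([
            (last_climate[c] - lo) / (hi - lo)
            for c, (lo, hi) in OBS_CLIMATE_RANGES.items()])
        self._last_crop_obs = crop_norm
        self._last_resource_obs = np.array([
            res_tuple[0] / cfg.max_heat,
            res_tuple[1] / cfg.max_co2,
            (res_tuple[2] + res_tuple[3]) / cfg.max_electricity,
            res_tuple[4] / cfg.max_irrigation,
            self._cum_truss / (cfg.max_cum_trusses * cfg.max_steps),
        ])
        self._prev_action = action

        info = {
            "week": self._week,
            "timesteps_advanced": TIMESTEPS_PER_WEEK,
            "reward_breakdown": breakdown.as_dict(),
            "setpoints": {c: getattr(setpoints, c)
                          for c in ACTION_COMPONENTS},
            "weekly_resources": dict(zip(
                ("heat", "co2", "elec_high", "elec_low", "irrigation"),
                res_tuple)),
            "cumulative_resources": dict(zip(
                ("heat", "co2", "elec_high", "elec_low", "irrigation"),
                self._cum_resources.tolist())),
            "crop_increments": {"Stem_elong": inc[0], "Stem_thick": inc[1],
                                "Truss_inc": inc[2]},
            "cum_truss": self._cum_truss,
            "overuse": overuse_flags,
        }
        if self.log_path is not None:
            with open(self.log_path, "a") as fh:
                fh.write(json.dumps(
                    {"week": self._week, "action": action.tolist(),
                     **{k: info[k] for k in ("reward_breakdown", "setpoints",
                                             "weekly_resources")}}) + "\n")
        return (self._observation(), float(breakdown.total),
                bool(terminated), bool(truncated), info)
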