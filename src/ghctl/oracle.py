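"""Parametric ground-truth greenhouse dynamics.

This module is a compact, seeded stand-in for a physical greenhouse
compartment: first-order relaxation dynamics for the indoor climate, daily
resource-consumption accounting, and weekly saturating crop-growth responses.
It emits linked tables in the autonomous-greenhouse-challenge layout (outside
weather, control setpoints, hourly indoor climate, daily resources, weekly
crop observations) for surrogate-estimator training, and doubles as a
brute-force reference backend for environment tests.

It is intentionally not a physics-grade model: each climate channel relaxes
toward a setpoint/weather-driven target with qualitatively correct couplings
(solar gain heats, ventilation leaks CO₂, screens shade), which is sufficient
for training estimators and exercising a control agent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .weather import (
    RECORDS_PER_DAY,
    WeatherGenConfig,
    _saturation_vapour_density,
    generate_weather,
)

HOURS_PER_DAY = 24
HOURS_PER_WEEK = 168
DAYS_PER_WEEK = 7
TIMESTEPS_PER_WEEK = DAYS_PER_WEEK * RECORDS_PER_DAY  # 2016

#: Control-setpoint column order (challenge Table-2 layout).
SETPOINT_COLUMNS = [
    "CO2_sp", "dx_sp", "t_rail_min_sp", "t_grow_min_sp", "Assim_sp",
    "scr_enrg_sp", "scr_blck_sp", "t_heat_sp", "t_vent_sp",
    "window_pos_lee_sp", "water_sup_int_sp_min",
    "int_blue_sp", "int_red_sp", "int_farred_sp", "int_white_sp",
    "pH_drain_sp",
]

#: Indoor-climate column order (challenge Table-3 layout).
CLIMATE_COLUMNS = [
    "Tair", "Rhair", "CO2air", "HumDef", "VentLee", "Ventwind",
    "AssimLight", "EnScr", "BlackScr", "PipeLow", "PipeGrow", "CO2_dos",
    "Tot_PAR", "Tot_PAR_Lamps", "EC_drain_PC", "pH_drain_PC",
    "Water_sup", "Cum_irr",
]

#: Auxiliary columns carried alongside the climate table (dropped on save).
CLIMATE_AUX_COLUMNS = ["_heat_demand", "_lamp_kw", "_Tout", "_Iglob"]

RESOURCE_COLUMNS = ["Heat_cons", "ElecHigh", "ElecLow", "CO2_cons", "Irr"]
CROP_COLUMNS = ["Stem_elong", "Stem_thick", "Cum_truss"]


@dataclass
class SetpointVector:
    """One weekly vector of greenhouse control setpoints.

    Fields mirror the challenge control-setpoint table; ``pH_drain_sp`` is the
    drain-pH target tracked by the measured ``pH_drain_PC`` state (the drain
    pH appears both as an agent action and as an observed state; we interpret
    the state as tracking the setpoint).
    """

    CO2_sp: float = 600.0              # ppm
    dx_sp: float = 2.0                 # g/m³ humidity-deficit target
    t_rail_min_sp: float = 35.0        # °C
    t_grow_min_sp: float = 30.0        # °C
    Assim_sp: float = 50.0             # % HPS lighting
    scr_enrg_sp: float = 0.0           # % energy curtain
    scr_blck_sp: float = 0.0           # % blackout curtain
    t_heat_sp: float = 18.0            # °C
    t_vent_sp: float = 22.0            # °C
    window_pos_lee_sp: float = 100.0   # % max lee-window position
    water_sup_int_sp_min: float = 120.0  # minutes between irrigation events
    int_blue_sp: float = 0.0           # [0-1000] LED channel intensities
    int_red_sp: float = 0.0
    int_farred_sp: float = 0.0
    int_white_sp: float = 200.0
    pH_drain_sp: float = 5.5

    RANGES = {
        "CO2_sp": (0.0, 2000.0), "dx_sp": (0.0, 10.0),
        "t_rail_min_sp": (0.0, 60.0), "t_grow_min_sp": (0.0, 60.0),
        "Assim_sp": (0.0, 100.0), "scr_enrg_sp": (0.0, 100.0),
        "scr_blck_sp": (0.0, 100.0), "t_heat_sp": (0.0, 35.0),
        "t_vent_sp": (0.0, 40.0), "window_pos_lee_sp": (0.0, 100.0),
        "water_sup_int_sp_min": (5.0, 1440.0),
        "int_blue_sp": (0.0, 1000.0), "int_red_sp": (0.0, 1000.0),
        "int_farred_sp": (0.0, 1000.0), "int_white_sp": (0.0, 1000.0),
        "pH_drain_sp": (4.0, 8.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def replace(self, **kw) -> "SetpointVector":
        return dataclasses.replace(self, **kw)

    def as_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in SETPOINT_COLUMNS})


@dataclass
class OracleParams:
    """Coefficients of the parametric greenhouse dynamics."""

    # Climate
    thermal_relax: float = 0.7          # per hour, toward the thermal target
    weight_heat: float = 0.35           # convex weights of the thermal target
    weight_vent: float = 0.25
    weight_out: float = 0.40
    solar_heat_gain: float = 0.012      # °C per W/m² of transmitted sun
    screen_insulation: float = 0.35     # demand reduction, energy screen closed
    co2_relax: float = 0.8              # per hour, toward CO2 setpoint
    vent_leak_rate: float = 0.5         # CO2 leak per unit vent opening
    co2_base_leak: float = 0.05         # infiltration leak fraction per hour
    co2_uptake_per_par: float = 0.05    # ppm/h drawn down per µmol/m²·s PAR
    co2_ambient: float = 420.0          # ppm outside
    par_transmission: float = 0.60      # glass transmission for sun PAR
    blackout_shade: float = 0.90        # PAR blocked by closed blackout screen
    energy_screen_shade: float = 0.25   # PAR blocked by closed energy screen
    lamp_on_iglob: float = 50.0         # W/m² below which lamps switch on
    hps_par: float = 180.0              # µmol/m²·s at 100% HPS
    led_par: float = 120.0              # µmol/m²·s at intensity 1000
    hps_power: float = 0.085            # kW/m² at 100% HPS
    led_power: float = 0.055            # kW/m² at intensity 1000
    vent_gain: float = 25.0             # % opening per °C above t_vent_sp

    # Resources
    heat_coeff: float = 0.055           # MJ/m² per degree-hour of demand
    co2_dos_gain: float = 0.5           # kg/ha·h per ppm/h of injection
    irr_event_volume: float = 0.28      # L/m² per supply event
    irr_event_minutes: float = 3.0      # valve-open minutes per event
    irr_window_minutes: float = 960.0   # daily irrigation window (04:00-20:00)
    irr_radiation_coeff: float = 0.5    # radiation scaling of event volume

    # Crop response
    t_opt_low: float = 19.0             # °C, optimal air-temperature band
    t_opt_high: float = 23.0
    t_response_width: float = 4.0       # °C, falloff scale outside the band
    par_saturation: float = 60.0        # mol/m²·week, half-saturation
    par_optimum: float = 180.0          # mol/m²·week (~26 mol/m²·day DLI,
                                        # the commercial tomato light target)
    co2_optimum: float = 800.0          # ppm
    co2_response_slope: float = 0.4     # exponent of the CO2 response
    water_adequacy_weight: float = 0.5  # exponent of the water response
    water_demand: float = 14.0          # L/m²·week of full-adequacy irrigation
    max_stem_elong: float = 18.0        # cm/week at optimal conditions
    max_stem_thick: float = 1.1         # mm/week
    max_truss_rate: float = 1.3         # new trusses/stem·week

    # Observation noise (set to 0 for closed-form checks)
    noise_tair: float = 0.15
    noise_rh: float = 1.0
    noise_co2: float = 8.0
    noise_crop: float = 0.01            # relative, on weekly increments
    ec_drift: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_opt_low < self.t_opt_high:
            raise ValueError("optimal temperature band must have low < high")
        for name in ("thermal_relax", "co2_relax", "heat_coeff",
                     "irr_event_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "OracleParams":
        return dataclasses.replace(self, **kw)

    def no_noise(self) -> "OracleParams":
        return self.replace(noise_tair=0.0, noise_rh=0.0, noise_co2=0.0,
                            noise_crop=0.0, ec_drift=0.0)


def _schedule_frame(setpoints, index: pd.DatetimeIndex) -> pd.DataFrame:
    """Broadcast a SetpointVector (or accept a frame) onto an hourly index."""
    if isinstance(setpoints, SetpointVector):
        row = setpoints.as_series()
        return pd.DataFrame([row.values] * len(index), columns=row.index,
                            index=index)
    missing = [c for c in SETPOINT_COLUMNS if c not in setpoints.columns]
    if missing:
        raise ValueError(f"setpoint schedule missing columns: {missing}")
    return setpoints.reindex(index, method="ffill")


def simulate_climate(weather: pd.DataFrame, setpoints, params: OracleParams,
                     rng: np.random.Generator | None = None,
                     init_tair: float | None = None,
                     init_co2: float | None = None,
                     hourly: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate the hourly indoor climate for the weather horizon.

    ``setpoints`` is a single :class:`SetpointVector` held constant or an
    hourly schedule frame.  Returns a frame with the standard climate columns
    plus auxiliary ``_``-prefixed columns used by the resource accounting.
    ``hourly`` may pass precomputed hourly weather means to skip resampling.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_hours = len(weather) // 12
    if n_hours * 12 != len(weather):
        raise ValueError("weather horizon must cover whole hours")

    if hourly is None:
        hourly = weather.resample("1h").mean()
    if len(hourly) != n_hours:
        raise ValueError("weather index does not align with the hourly grid")
    sp = _schedule_frame(setpoints, hourly.index)

    tout = hourly["Tout"].to_numpy()
    iglob = hourly["Iglob"].to_numpy()
    hour_of_day = hourly.index.hour.to_numpy()

    co2_sp = sp["CO2_sp"].to_numpy()
    t_heat = sp["t_heat_sp"].to_numpy()
    t_vent = sp["t_vent_sp"].to_numpy()
    scr_enrg = sp["scr_enrg_sp"].to_numpy()
    scr_blck = sp["scr_blck_sp"].to_numpy()
    assim = sp["Assim_sp"].to_numpy()
    window_cap = sp["window_pos_lee_sp"].to_numpy()
    dx_sp = sp["dx_sp"].to_numpy()
    interval = sp["water_sup_int_sp_min"].to_numpy()
    led_total = (sp["int_blue_sp"] + sp["int_red_sp"] + sp["int_farred_sp"]
                 + sp["int_white_sp"]).to_numpy() / 1000.0
    ph_sp = sp["pH_drain_sp"].to_numpy()

    # Light: sun PAR through glass and screens, lamps on in dark hours.
    shade = ((1.0 - params.blackout_shade * scr_blck / 100.0)
             * (1.0 - params.energy_screen_shade * scr_enrg / 100.0))
    sun_par = iglob * 2.1 * params.par_transmission * shade
    lamps_on = (iglob < params.lamp_on_iglob).astype(float)
    assim_light = assim * lamps_on
    lamp_par = (params.hps_par * assim_light / 100.0
                + params.led_par * led_total * lamps_on)
    lamp_kw = (params.hps_power * assim_light / 100.0
               + params.led_power * led_total * lamps_on)
    tot_par = sun_par + lamp_par

    # Irrigation: events spaced by the supply interval within a fixed
    # daily window, volume scaled by the day's radiation.
    in_window = ((hour_of_day >= 4) & (hour_of_day < 20)).astype(float)
    events_per_hour = in_window * 60.0 / np.maximum(interval, 1.0)
    day_index = np.arange(n_hours) // HOURS_PER_DAY
    day_mean_iglob = np.bincount(day_index, weights=iglob) / HOURS_PER_DAY
    rad_factor = 1.0 + params.irr_radiation_coeff * (
        day_mean_iglob[day_index] / 300.0)
    irr_per_hour = events_per_hour * params.irr_event_volume * rad_factor

    w = np.array([params.weight_heat, params.weight_vent, params.weight_out])
    w = w / w.sum()

    tair = np.empty(n_hours)
    rhair = np.empty(n_hours)
    co2air = np.empty(n_hours)
    co2_dos = np.empty(n_hours)
    heat_demand = np.empty(n_hours)
    ec = np.empty(n_hours)
    ph = np.empty(n_hours)

    solar_gain = params.solar_heat_gain * iglob * shade
    target_base = w[0] * t_heat + w[1] * t_vent + w[2] * tout + solar_gain

    t_prev = target_base[0] if init_tair is None else init_tair
    c_prev = co2_sp[0] if init_co2 is None else init_co2
    ec_prev, ph_prev = 2.8, ph_sp[0]
    k_t, k_c = params.thermal_relax, params.co2_relax
    for h in range(n_hours):
        t_new = t_prev + k_t * (target_base[h] - t_prev)
        # Heating demand before ventilation: degrees below the heating target.
        demand = max(0.0, t_heat[h] - t_new) * (
            1.0 - params.screen_insulation * scr_enrg[h] / 100.0)
        t_new = max(t_new, t_heat[h] - 0.5 * demand)
        vent_open = min(window_cap[h],
                        max(0.0, (t_new - t_vent[h]) * params.vent_gain))
        # Bounded-slope vent cooling keeps Tair monotone in the setpoints.
        t_new -= 0.2 * (vent_open / 100.0) * 10.0 * np.tanh(
            max(0.0, t_new - tout[h]) / 10.0)

        # CO2 mass balance in ppm/h: leaks (infiltration + ventilation) and
        # photosynthetic draw-down must be replenished by dosing for the
        # concentration to track its setpoint.
        losses = ((params.co2_base_leak
                   + params.vent_leak_rate * vent_open / 100.0)
                  * max(0.0, c_prev - params.co2_ambient)
                  + params.co2_uptake_per_par * tot_par[h])
        injection = max(0.0, k_c * (co2_sp[h] - c_prev) + losses)
        dosing = params.co2_dos_gain * injection
        if injection > 0.0:
            c_new = c_prev + k_c * (co2_sp[h] - c_prev)
        else:
            c_new = c_prev - losses
        c_new = max(c_new, params.co2_ambient * 0.9)

        ec_prev = ec_prev + params.ec_drift * rng.normal() if params.ec_drift else ec_prev
        ph_prev = ph_prev + 0.2 * (ph_sp[h] - ph_prev) + (
            0.5 * params.ec_drift * rng.normal() if params.ec_drift else 0.0)

        tair[h], co2air[h] = t_new, c_new
        co2_dos[h], heat_demand[h] = dosing, demand
        ec[h], ph[h] = ec_prev, ph_prev
        t_prev, c_prev = t_new, c_new

    if params.noise_tair:
        tair = tair + rng.normal(0.0, params.noise_tair, n_hours)
    if params.noise_co2:
        co2air = np.clip(co2air + rng.normal(0.0, params.noise_co2, n_hours),
                         0.0, None)

    # Humidity: deficit relaxes toward its setpoint, worse when vents closed.
    vent_open = np.minimum(window_cap,
                           np.maximum(0.0, (tair - t_vent) * params.vent_gain))
    humdef = np.clip(dx_sp + 0.4 * (1.0 - vent_open / 100.0)
                     - 0.002 * irr_per_hour * 10.0, 0.05, None)
    svd = _saturation_vapour_density(tair)
    rhair = np.clip(100.0 * (1.0 - humdef / svd), 0.0, 100.0)
    if params.noise_rh:
        rhair = np.clip(rhair + rng.normal(0.0, params.noise_rh, n_hours),
                        0.0, 100.0)
        humdef = np.clip(svd * (1.0 - rhair / 100.0), 0.0, None)

    pipe_low = np.maximum(sp["t_rail_min_sp"].to_numpy(),
                          tair + 8.0 * np.tanh(heat_demand))
    pipe_grow = np.maximum(sp["t_grow_min_sp"].to_numpy(),
                           tair + 5.0 * np.tanh(heat_demand))

    minutes = events_per_hour * params.irr_event_minutes
    water_sup = (minutes.reshape(-1, HOURS_PER_DAY).cumsum(axis=1)
                 .reshape(-1)) if n_hours % HOURS_PER_DAY == 0 else np.cumsum(minutes)
    cum_irr = (irr_per_hour.reshape(-1, HOURS_PER_DAY).cumsum(axis=1)
               .reshape(-1)) if n_hours % HOURS_PER_DAY == 0 else np.cumsum(irr_per_hour)

    out = pd.DataFrame({
        "Tair": tair,
        "Rhair": rhair,
        "CO2air": co2air,
        "HumDef": humdef,
        "VentLee": vent_open,
        "Ventwind": 0.6 * vent_open,
        "AssimLight": assim_light,
        "EnScr": scr_enrg,
        "BlackScr": scr_blck,
        "PipeLow": pipe_low,
        "PipeGrow": pipe_grow,
        "CO2_dos": co2_dos,
        "Tot_PAR": tot_par,
        "Tot_PAR_Lamps": lamp_par,
        "EC_drain_PC": ec,
        "pH_drain_PC": ph,
        "Water_sup": water_sup,
        "Cum_irr": cum_irr,
        "_heat_demand": heat_demand,
        "_lamp_kw": lamp_kw,
        "_Tout": tout,
        "_Iglob": iglob,
    }, index=hourly.index)
    return out


def simulate_resources(climate: pd.DataFrame, setpoints,
                       params: OracleParams) -> pd.DataFrame:
    """Aggregate hourly climate into daily resource consumption."""
    n_hours = len(climate)
    if n_hours % HOURS_PER_DAY != 0:
        raise ValueError("climate series must span whole days")
    hour_of_day = pd.DatetimeIndex(climate.index).hour.to_numpy()
    day_index = np.arange(n_hours) // HOURS_PER_DAY
    n_days = n_hours // HOURS_PER_DAY

    heat = params.heat_coeff * climate["_heat_demand"].to_numpy()
    lamp_kw = climate["_lamp_kw"].to_numpy()
    peak = (hour_of_day >= 7) & (hour_of_day < 23)
    elec_high = np.bincount(day_index, weights=lamp_kw * peak,
                            minlength=n_days)
    elec_low = np.bincount(day_index, weights=lamp_kw * ~peak,
                           minlength=n_days)
    heat_cons = np.bincount(day_index, weights=heat, minlength=n_days)
    co2_cons = np.bincount(day_index, weights=climate["CO2_dos"].to_numpy(),
                           minlength=n_days) / 1e4  # kg/ha·h → kg/m²·day
    irr_hourly = np.diff(
        np.concatenate([[0.0], climate["Cum_irr"].to_numpy()]))
    irr_hourly[irr_hourly < 0] = climate["Cum_irr"].to_numpy()[irr_hourly < 0]
    irr = np.bincount(day_index, weights=irr_hourly, minlength=n_days)

    index = pd.DatetimeIndex(climate.index).normalize().unique()
    return pd.DataFrame({
        "Heat_cons": heat_cons,
        "ElecHigh": elec_high,
        "ElecLow": elec_low,
        "CO2_cons": co2_cons,
        "Irr": irr,
    }, index=index[:n_days])


def weekly_aggregates(climate: pd.DataFrame, resources: pd.DataFrame,
                      params: OracleParams) -> pd.DataFrame:
    """Reduce hourly climate + daily resources to weekly crop drivers."""
    n_weeks = len(climate) // HOURS_PER_WEEK
    if n_weeks * HOURS_PER_WEEK != len(climate):
        raise ValueError("climate series must span whole weeks")
    week_h = np.arange(len(climate)) // HOURS_PER_WEEK
    week_d = np.arange(len(resources)) // DAYS_PER_WEEK
    mean = lambda col: np.bincount(week_h, weights=climate[col].to_numpy(),
                                   minlength=n_weeks) / HOURS_PER_WEEK
    par_mol = np.bincount(
        week_h, weights=climate["Tot_PAR"].to_numpy(),
        minlength=n_weeks) * 3600.0 / 1e6  # µmol/m²·s·h → mol/m²·week
    irr_week = np.bincount(week_d, weights=resources["Irr"].to_numpy(),
                           minlength=n_weeks)
    return pd.DataFrame({
        "mean_Tair": mean("Tair"),
        "par_mol": par_mol,
        "mean_CO2air": mean("CO2air"),
        "water_adequacy": np.clip(irr_week / params.water_demand, 0.0, 1.0),
    }, index=pd.RangeIndex(n_weeks, name="week"))


def crop_response_factors(agg: pd.DataFrame,
                          params: OracleParams) -> pd.DataFrame:
    """Multiplicative response factors in [0, 1] per weekly aggregate row."""
    for col in ("mean_Tair", "par_mol", "mean_CO2air", "water_adequacy"):
        if col not in agg.columns:
            raise ValueError(f"weekly aggregates missing column: {col}")
    t = agg["mean_Tair"].to_numpy()
    outside = np.maximum(params.t_opt_low - t, 0.0) + np.maximum(
        t - params.t_opt_high, 0.0)
    f_t = np.exp(-((outside / params.t_response_width) ** 2))
    par = agg["par_mol"].to_numpy()
    sat = par / (par + params.par_saturation)
    sat_opt = params.par_optimum / (params.par_optimum + params.par_saturation)
    f_par = np.clip(sat / sat_opt, 0.0, 1.0)
    f_co2 = np.clip(agg["mean_CO2air"].to_numpy() / params.co2_optimum,
                    0.0, 1.0) ** params.co2_response_slope
    f_w = np.clip(agg["water_adequacy"].to_numpy(),
                  0.0, 1.0) ** params.water_adequacy_weight
    return pd.DataFrame({"f_t": f_t, "f_par": f_par, "f_co2": f_co2,
                         "f_w": f_w}, index=agg.index)


def simulate_crop(agg: pd.DataFrame, params: OracleParams,
                  rng: np.random.Generator | None = None,
                  cum_truss_start: float = 0.0) -> pd.DataFrame:
    """Weekly crop increments from weekly climate aggregates.

    Increments are smooth saturating functions of the aggregates, equal to
    the configured maxima when every driver sits at its optimum, and
    ``Cum_truss`` accumulates across weeks.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    f = crop_response_factors(agg, params)
    growth = (f["f_t"] * f["f_par"] * f["f_co2"] * f["f_w"]).to_numpy()
    if params.noise_crop:
        growth = growth * np.clip(
            1.0 + rng.normal(0.0, params.noise_crop, len(growth)), 0.0, None)
    elong = params.max_stem_elong * growth
    thick = params.max_stem_thick * growth
    truss = cum_truss_start + np.cumsum(params.max_truss_rate * growth)
    return pd.DataFrame({"Stem_elong": elong, "Stem_thick": thick,
                         "Cum_truss": truss}, index=agg.index)


def random_policy(rng: np.random.Generator) -> SetpointVector:
    """A horticulturally plausible randomized weekly setpoint vector."""
    t_heat = float(rng.uniform(14.0, 24.0))
    return SetpointVector(
        CO2_sp=float(rng.uniform(400.0, 1000.0)),
        dx_sp=float(rng.uniform(1.0, 4.0)),
        t_rail_min_sp=float(rng.uniform(30.0, 45.0)),
        t_grow_min_sp=float(rng.uniform(25.0, 40.0)),
        Assim_sp=float(rng.uniform(0.0, 100.0)),
        scr_enrg_sp=float(rng.choice([0.0, 100.0])),
        scr_blck_sp=float(rng.choice([0.0, 0.0, 100.0])),
        t_heat_sp=t_heat,
        t_vent_sp=float(rng.uniform(max(t_heat + 1.0, 16.0), 30.0)),
        window_pos_lee_sp=float(rng.uniform(50.0, 100.0)),
        water_sup_int_sp_min=float(rng.uniform(30.0, 360.0)),
        int_blue_sp=float(rng.uniform(0.0, 200.0)),
        int_red_sp=float(rng.uniform(0.0, 200.0)),
        int_farred_sp=float(rng.uniform(0.0, 100.0)),
        int_white_sp=float(rng.uniform(0.0, 1000.0)),
        pH_drain_sp=float(rng.uniform(5.0, 6.5)),
    )


def make_dataset(weeks: int, params: OracleParams | None = None,
                 seed: int = 0, setpoint_policy=None,
                 weather_config: WeatherGenConfig | None = None) -> dict:
    """Generate a linked synthetic dataset in the challenge table layout.

    Returns a dict of frames: ``weather`` (5-min), ``setpoints`` (weekly),
    ``climate`` (hourly), ``resources`` (daily), ``crop`` (weekly).
    """
    if weeks < 1:
        raise ValueError(f"weeks must be >= 1, got {weeks}")
    params = params or OracleParams()
    rng = np.random.default_rng(seed)
    if weather_config is None:
        weather_config = WeatherGenConfig(n_days=weeks * DAYS_PER_WEEK,
                                          seed=int(rng.integers(2 ** 31)))
    else:
        weather_config = weather_config.replace(n_days=weeks * DAYS_PER_WEEK)
    weather = generate_weather(weather_config)
    policy = setpoint_policy or (lambda week, r: random_policy(r))

    sp_rows, climate_parts, resource_parts = [], [], []
    sim_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    hourly_all = weather.resample("1h").mean()
    init_t, init_c = None, None
    for week in range(weeks):
        sp = policy(week, rng)
        wslice = weather.iloc[week * TIMESTEPS_PER_WEEK:
                              (week + 1) * TIMESTEPS_PER_WEEK]
        hslice = hourly_all.iloc[week * HOURS_PER_WEEK:
                                 (week + 1) * HOURS_PER_WEEK]
        climate = simulate_climate(wslice, sp, params, rng=sim_rng,
                                   init_tair=init_t, init_co2=init_c,
                                   hourly=hslice)
        resources = simulate_resources(climate, sp, params)
        init_t = float(climate["Tair"].iloc[-1])
        init_c = float(climate["CO2air"].iloc[-1])
        sp_rows.append(sp.as_series())
        climate_parts.append(climate)
        resource_parts.append(resources)

    climate_all = pd.concat(climate_parts)
    resources_all = pd.concat(resource_parts)
    agg = weekly_aggregates(climate_all, resources_all, params)
    crop = simulate_crop(agg, params, rng=sim_rng)
    setpoints = pd.DataFrame(sp_rows,
                             index=pd.RangeIndex(weeks, name="week"))
    return {
        "weather": weather,
        "setpoints": setpoints,
        "climate": climate_all,
        "resources": resources_all,
        "crop": crop,
        "aggregates": agg,
    }


def save_dataset(tables: dict, outdir) -> None:
    """Write a dataset to CSV files (auxiliary climate columns dropped)."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables["weather"].to_csv(out / "weather.csv", index_label="time")
    tables["setpoints"].to_csv(out / "setpoints.csv", index_label="week")
    tables["climate"][CLIMATE_COLUMNS].to_csv(out / "climate.csv",
                                              index_label="time")
    tables["resources"].to_csv(out / "resources.csv", index_label="day")
    tables["crop"].to_csv(out / "crop.csv", index_label="week")
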