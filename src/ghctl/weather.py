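"""Seeded synthetic outside-weather generation on a 5-minute grid.

The generator produces the ten outside-weather channels used throughout the
package (temperature, humidity, solar radiation, wind, rain, ...) with
seasonal and diurnal structure, AR(1) short-term persistence, and optional
multi-day extreme regimes: heatwaves, cold spells, and prolonged low-radiation
periods.  Column names and units follow the autonomous-greenhouse-challenge
table layout so real CSV exports drop in unchanged.

Each channel is modelled as

    x(t) = seasonal(t) + diurnal(t) + AR1 noise(t) + regime offset(t)

except the solar channels (``Iglob``, ``PARout``), which use a clear-sky
half-sine over the daylight window multiplied by a stochastic cloudiness
factor and are exactly zero at night.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RECORDS_PER_DAY = 288  # 5-minute cadence
CADENCE_MINUTES = 5

#: Column order of the outside-weather table.
WEATHER_COLUMNS = [
    "Tout", "Rhout", "Iglob", "Windsp", "Winddir",
    "RadSum", "PARout", "Pyrogeo", "Rain", "AbsHumOut",
]

# µmol photons per joule of global radiation (PAR fraction ~0.45, ~4.6 µmol/J
# within the PAR band).
_PAR_PER_WATT = 2.1


class WeatherSchemaError(ValueError):
    """A weather table is missing a required column."""


class WeatherValidationError(ValueError):
    """A weather table violates a record invariant."""


@dataclass(frozen=True)
class RegimeEvent:
    """A multi-day extreme-weather regime affecting one channel."""

    kind: str            # "heatwave" | "cold_spell" | "low_radiation"
    start_day: int
    duration_days: int

    @property
    def end_day(self) -> int:
        return self.start_day + self.duration_days


@dataclass
class WeatherGenConfig:
    """Configuration of the stochastic weather generator.

    Defaults describe a temperate spring-to-autumn tomato season: mild
    temperatures with a pronounced diurnal cycle, moderate humidity, and
    occasional multi-day extremes.  Rates are per-day probabilities that a
    regime event begins on a given day.
    """

    n_days: int = 7
    start_day_of_year: int = 60
    cadence_minutes: int = CADENCE_MINUTES

    # Seasonal (annual sinusoid) mean and amplitude, diurnal amplitude.
    temp_mean: float = 12.0
    temp_seasonal_amplitude: float = 8.0
    temp_diurnal_amplitude: float = 4.0
    rh_mean: float = 75.0
    rh_seasonal_amplitude: float = 5.0
    rh_diurnal_amplitude: float = 10.0
    wind_mean: float = 3.5
    wind_seasonal_amplitude: float = 1.0

    # Clear-sky solar peak (W/m²) at summer solstice and its seasonal swing.
    solar_peak: float = 850.0
    solar_seasonal_amplitude: float = 350.0
    daylight_hours_mean: float = 12.0
    daylight_hours_amplitude: float = 3.5

    # AR(1) persistence and innovation scale per channel.
    temp_persistence: float = 0.98
    temp_noise: float = 0.12
    rh_persistence: float = 0.97
    rh_noise: float = 0.6
    wind_persistence: float = 0.95
    wind_noise: float = 0.25
    cloud_persistence: float = 0.995
    cloud_noise: float = 0.02

    # Extreme regimes: per-day start probability, duration range (days),
    # and effect size.
    heatwave_rate: float = 0.02
    heatwave_duration: tuple[int, int] = (2, 5)
    heatwave_offset: float = 8.0          # °C added to Tout
    cold_spell_rate: float = 0.02
    cold_spell_duration: tuple[int, int] = (2, 5)
    cold_spell_offset: float = -7.0       # °C added to Tout
    low_radiation_rate: float = 0.03
    low_radiation_duration: tuple[int, int] = (2, 4)
    low_radiation_factor: float = 0.25    # multiplies the cloudiness factor

    rain_probability: float = 0.08        # per hour
    rain_persistence: float = 0.75        # P(rain continues next hour)

    noise_enabled: bool = True
    events_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        for name in ("heatwave_rate", "cold_spell_rate", "low_radiation_rate",
                     "rain_probability", "rain_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("temp_persistence", "rh_persistence", "wind_persistence",
                     "cloud_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("heatwave_duration", "cold_spell_duration",
                     "low_radiation_duration"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi")

    def replace(self, **kw) -> "WeatherGenConfig":
        return dataclasses.replace(self, **kw)


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) path with marginal sd sigma/sqrt(1-rho^2)."""
    from scipy.signal import lfilter

    eps = rng.normal(0.0, sigma, size=n)
    eps[0] *= 1.0 / np.sqrt(1.0 - rho * rho)
    return lfilter([1.0], [1.0, -rho], eps)


def sample_events(config: WeatherGenConfig,
                  rng: np.random.Generator) -> list[RegimeEvent]:
    """Sample regime events for the horizon. Deterministic given rng state."""
    events: list[RegimeEvent] = []
    if not config.events_enabled:
        return events
    specs = [
        ("heatwave", config.heatwave_rate, config.heatwave_duration),
        ("cold_spell", config.cold_spell_rate, config.cold_spell_duration),
        ("low_radiation", config.low_radiation_rate,
         config.low_radiation_duration),
    ]
    for kind, rate, (dlo, dhi) in specs:
        day = 0
        while day < config.n_days:
            if rng.random() < rate:
                dur = int(rng.integers(dlo, dhi + 1))
                events.append(RegimeEvent(kind, day, dur))
                day += dur  # events of one kind do not overlap
            else:
                day += 1
    return events


def _event_mask(events: list[RegimeEvent], kind: str, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for ev in events:
        if ev.kind == kind:
            mask[ev.start_day * RECORDS_PER_DAY:ev.end_day * RECORDS_PER_DAY] = True
    return mask


def event_coverage(events: list[RegimeEvent], kind: str, n_days: int) -> float:
    """Fraction of the horizon covered by events of the given kind."""
    mask = _event_mask(events, kind, n_days * RECORDS_PER_DAY)
    return float(mask.mean())


def _saturation_vapour_density(temp_c: np.ndarray) -> np.ndarray:
    """Approximate saturation water-vapour density (g/m³) vs temperature."""
    return (5.018 + 0.32321 * temp_c + 8.1847e-3 * temp_c ** 2
            + 3.1243e-4 * temp_c ** 3).clip(min=0.1)


def generate_weather(config: WeatherGenConfig,
                     return_events: bool = False):
    """Generate a seeded synthetic weather series.

    Returns a DataFrame with one row per 5-minute record, a ``time`` index,
    and the standard outside-weather columns.  With ``return_events`` the
    sampled regime events are returned alongside as ``(frame, events)``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_days * RECORDS_PER_DAY

    day_frac = (np.arange(n) % RECORDS_PER_DAY) / RECORDS_PER_DAY  # [0,1)
    day_of_year = config.start_day_of_year + np.arange(n) / RECORDS_PER_DAY

    # Annual cycle peaking around day 196 (mid-July).
    season = np.sin(2.0 * np.pi * (day_of_year - 105.0) / 365.0)

    events = sample_events(config, rng)

    # --- temperature ------------------------------------------------------
    temp = (config.temp_mean
            + config.temp_seasonal_amplitude * season
            # diurnal minimum near 05:00, maximum near 15:00
            + config.temp_diurnal_amplitude
            * np.sin(2.0 * np.pi * (day_frac - 10.0 / 24.0)))
    if config.noise_enabled:
        temp = temp + _ar1(rng, n, config.temp_persistence, config.temp_noise)
    temp = temp + config.heatwave_offset * _event_mask(events, "heatwave", n)
    temp = temp + config.cold_spell_offset * _event_mask(events, "cold_spell", n)

    # --- solar ------------------------------------------------------------
    daylight = (config.daylight_hours_mean
                + config.daylight_hours_amplitude * season) / 24.0
    sunrise = 0.5 - daylight / 2.0
    sunset = 0.5 + daylight / 2.0
    in_day = (day_frac >= sunrise) & (day_frac < sunset)
    phase = np.where(in_day, (day_frac - sunrise) / np.maximum(daylight, 1e-9),
                     0.0)
    clear_sky = (config.solar_peak
                 - config.solar_seasonal_amplitude * (1.0 - season) / 2.0)
    clear_sky = np.clip(clear_sky, 50.0, None)
    halfsine = np.where(in_day, np.sin(np.pi * phase), 0.0)
    if config.noise_enabled:
        cloud = 1.0 / (1.0 + np.exp(-(
            1.2 + _ar1(rng, n, config.cloud_persistence, config.cloud_noise) * 8.0)))
    else:
        cloud = np.full(n, 1.0 / (1.0 + np.exp(-1.2)))
    low_rad = _event_mask(events, "low_radiation", n)
    cloud = np.where(low_rad, cloud * config.low_radiation_factor, cloud)
    iglob = clear_sky * halfsine * cloud
    iglob[~in_day] = 0.0
    parout = iglob * _PAR_PER_WATT

    # Running daily integral of Iglob in J/cm² (reset at midnight).
    step_j_per_cm2 = iglob * (config.cadence_minutes * 60.0) / 1e4
    radsum = (step_j_per_cm2
              .reshape(config.n_days, RECORDS_PER_DAY)
              .cumsum(axis=1)
              .reshape(n))

    # --- humidity ---------------------------------------------------------
    rh = (config.rh_mean
          - config.rh_seasonal_amplitude * season
          # humid at night, drier mid-afternoon (anti-phase with temperature)
          - config.rh_diurnal_amplitude
          * np.sin(2.0 * np.pi * (day_frac - 10.0 / 24.0)))
    if config.noise_enabled:
        rh = rh + _ar1(rng, n, config.rh_persistence, config.rh_noise)
    rh = np.clip(rh, 0.0, 100.0)
    abs_hum = _saturation_vapour_density(temp) * rh / 100.0

    # --- wind -------------------------------------------------------------
    wind = config.wind_mean + config.wind_seasonal_amplitude * (-season)
    if config.noise_enabled:
        wind = wind + _ar1(rng, n, config.wind_persistence, config.wind_noise)
    wind = np.clip(wind, 0.0, None)

    if config.noise_enabled:
        steps = rng.integers(-3, 4, size=n)
        winddir = np.mod(64 + np.cumsum(steps), 129)
        # reflect the bounded walk back into [0, 128]
        winddir = np.where(winddir > 128, 256 - winddir, winddir)
    else:
        winddir = np.full(n, 64)

    # --- rain (hourly Bernoulli with persistence, held for the hour) ------
    n_hours = config.n_days * 24
    rain_h = np.zeros(n_hours, dtype=np.int64)
    if config.noise_enabled and config.rain_probability > 0:
        u = rng.random(n_hours)
        rain_h[0] = u[0] < config.rain_probability
        for h in range(1, n_hours):
            p = (config.rain_persistence if rain_h[h - 1]
                 else config.rain_probability)
            rain_h[h] = u[h] < p
    rain = np.repeat(rain_h, 12)

    # Longwave balance: colder, clearer skies radiate more strongly.
    pyrgeo = -60.0 + 40.0 * cloud + 0.5 * (temp - config.temp_mean)

    index = pd.date_range(
        start=pd.Timestamp("2020-01-01")
        + pd.Timedelta(days=config.start_day_of_year - 1),
        periods=n, freq=f"{config.cadence_minutes}min", name="time")
    df = pd.DataFrame({
        "Tout": temp,
        "Rhout": rh,
        "Iglob": iglob,
        "Windsp": wind,
        "Winddir": winddir.astype(np.int64),
        "RadSum": radsum,
        "PARout": parout,
        "Pyrogeo": pyrgeo,
        "Rain": rain,
        "AbsHumOut": abs_hum,
    }, index=index)
    if return_events:
        return df, events
    return df


def validate_weather(df: pd.DataFrame) -> None:
    """Check the record invariants of a weather table; raise on violation."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherSchemaError(f"weather table missing columns: {missing}")
    if ((df["Rhout"] < 0) | (df["Rhout"] > 100)).any():
        raise WeatherValidationError("Rhout outside [0, 100]")
    if not df["Rain"].isin([0, 1]).all():
        raise WeatherValidationError("Rain must be binary {0, 1}")
    for col in ("Iglob", "Windsp", "RadSum", "PARout", "AbsHumOut"):
        if (df[col] < 0).any():
            raise WeatherValidationError(f"{col} must be non-negative")
    if ((df["Winddir"] < 0) | (df["Winddir"] > 128)).any():
        raise WeatherValidationError("Winddir outside [0, 128]")
    # RadSum non-decreasing within each calendar day
    days = pd.DatetimeIndex(df.index).normalize()
    if (df["RadSum"].groupby(days).diff().fillna(0.0) < -1e-9).any():
        raise WeatherValidationError("RadSum decreasing within a day")


def save_weather(df: pd.DataFrame, path) -> None:
    validate_weather(df)
    df.to_csv(path, index=True, index_label="time")


def load_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["time"], index_col="time")
    validate_weather(df)
    return df
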