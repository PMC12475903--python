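"""Synthetic weather, station networks and ground-truth LT50 generators.

Every pipeline stage is testable offline: this module fabricates GHCNd-
encoded daily weather (annual sinusoid + AR(1) noise + configurable
missingness), random station networks with a planted spatial damage field,
and a ground-truth LT50 series whose seasonal U-shape is driven by the same
thermal features the predictor consumes — chill accumulation pulls hardiness
toward the seasonal floor (acclimation) and recent heat pushes it back
toward the ceiling (deacclimation).

The truth model is deliberately expressible in the extracted features so
that regressor-recovery experiments have a well-defined target; it is a
test harness, not a claim about real grapevine physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ghcnd import DailySeries, StationMeta, write_dly, write_station_file
from .registry import CultivarRegistry

#: Day of year of the coldest day: mid-January north, mid-July south.
COLDEST_DOY_NORTH = 15
COLDEST_DOY_SOUTH = 196


@dataclass(frozen=True)
class WeatherGenConfig:
    """Parameters of the synthetic daily-weather process.

    Daily mean = annual_mean - annual_amplitude * cos(2*pi*(doy -
    coldest_doy)/365) + AR(1) noise; tmax/tmin sit half a diurnal range
    above/below the mean.  ``noise_sigma`` is the innovation standard
    deviation of the AR(1) process.
    """

    annual_mean_c: float = 8.0
    annual_amplitude_c: float = 14.0
    diurnal_range_c: float = 8.0
    ar1_coefficient: float = 0.7
    noise_sigma_c: float = 3.0
    missing_probability: float = 0.02
    years: int = 4
    start_year: int = 2000
    latitude: float = 43.0
    longitude: float = -76.0
    elevation_m: float = 120.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("AR(1) coefficient must be in [0, 1) for stationarity")
        if not 0.0 <= self.missing_probability < 1.0:
            raise ValueError("missing probability must be in [0, 1)")
        if self.years < 1:
            raise ValueError("need at least one year of weather")


@dataclass(frozen=True)
class Lt50GenConfig:
    """Parameters of the ground-truth LT50 process.

    truth = clamp(ceiling + (floor - ceiling) * A + gain * GDH10_recent
                  + cultivar_offset, floor, ceiling)

    where A = min(1, chill-hours / chill_requirement) is the normalized
    chilling status and GDH10_recent is an EWMA (span ``heat_span_days``) of
    the daily increments of cumulative growing degree hours above 10 C.
    Chilling deepens hardiness toward the floor; recent heat (deacclimation)
    raises LT50 back toward the ceiling.  Offsets must be <= 0 so that an
    unchilled, unheated vine sits exactly at ceiling + offset.
    """

    lt50_max_c: float = -8.0   # ceiling: least hardy
    lt50_min_c: float = -28.0  # floor: most hardy
    chill_requirement: float = 850.0  # chill hours to saturate acclimation
    heat_span_days: int = 7
    deacclimation_gain: float = 0.25  # degrees C per recent degree-hour
    noise_sigma_c: float = 1.0
    cultivar_offsets: dict = field(
        default_factory=lambda: {"vinifera": 0.0, "hybrid": -2.0}
    )

    def __post_init__(self) -> None:
        if not self.lt50_min_c < self.lt50_max_c <= 0.0:
            raise ValueError("need lt50_min < lt50_max <= 0")
        if any(v > 0 for v in self.cultivar_offsets.values()):
            raise ValueError("cultivar offsets must be <= 0 (ceiling is the clamp)")


def gen_weather_series(config: WeatherGenConfig, seed: int,
                       station_id: str = "SYN0000001") -> tuple[StationMeta, DailySeries]:
    """Generate one station's daily TMAX/TMIN record, fully seeded."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.years, month=1, day=1)
    dates = pd.date_range(start, end, freq="D", inclusive="left")
    doy = dates.dayofyear.to_numpy(dtype=float)
    coldest = COLDEST_DOY_NORTH if config.latitude >= 0 else COLDEST_DOY_SOUTH
    seasonal = config.annual_mean_c - config.annual_amplitude_c * np.cos(
        2.0 * np.pi * (doy - coldest) / 365.0
    )
    noise = np.empty(len(dates))
    prev = 0.0
    innovations = rng.normal(0.0, config.noise_sigma_c, size=len(dates))
    for i, eps in enumerate(innovations):
        prev = config.ar1_coefficient * prev + eps
        noise[i] = prev
    mean = seasonal + noise
    half = config.diurnal_range_c / 2.0
    frame = pd.DataFrame(
        {"tmax": mean + half, "tmin": mean - half}, index=dates
    )
    frame.index.name = "date"
    missing = rng.random(len(dates)) < config.missing_probability
    frame.loc[missing, ["tmax", "tmin"]] = np.nan
    meta = StationMeta(
        station_id=station_id,
        latitude=config.latitude,
        longitude=config.longitude,
        elevation=config.elevation_m,
        name=f"SYNTHETIC {station_id}",
    )
    return meta, DailySeries(station_id=station_id, data=frame)


def gen_station_weather(config: WeatherGenConfig, seed: int, out_dir: str | Path,
                        station_id: str = "SYN0000001") -> tuple[StationMeta, Path]:
    """Generate a station and write its record as a GHCNd ``.dly`` file."""
    meta, series = gen_weather_series(config, seed, station_id)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{station_id}.dly"
    write_dly(series, path)
    return meta, path


def gen_network(n_stations: int, bounds: tuple[float, float, float, float],
                damage_field, seed: int,
                prefix: str = "SYN") -> pd.DataFrame:
    """Scatter stations uniformly in a lat/lon box and sample a planted field.

    ``bounds`` is (lat_min, lat_max, lon_min, lon_max); ``damage_field`` is a
    function of (latitude, longitude) giving the planted truth value at each
    station.  Returns a frame with station_id, latitude, longitude, value —
    the recorded truth for recovery tests.
    """
    if n_stations < 1:
        raise ValueError("need at least one station")
    lat_min, lat_max, lon_min, lon_max = bounds
    if not (lat_min < lat_max and lon_min < lon_max):
        raise ValueError(f"degenerate bounds {bounds}")
    rng = np.random.default_rng(seed)
    lats = rng.uniform(lat_min, lat_max, size=n_stations)
    lons = rng.uniform(lon_min, lon_max, size=n_stations)
    values = np.array([damage_field(la, lo) for la, lo in zip(lats, lons)], dtype=float)
    ids = [f"{prefix}{i:07d}X" for i in range(n_stations)]
    return pd.DataFrame(
        {"station_id": ids, "latitude": lats, "longitude": lons, "value": values}
    )


def write_network(network: pd.DataFrame, destination: str | Path) -> None:
    """Write a generated network as a ghcnd-stations inventory file."""
    stations = [
        StationMeta(station_id=r.station_id, latitude=r.latitude,
                    longitude=r.longitude, name="SYNTHETIC NETWORK")
        for r in network.itertuples()
    ]
    write_station_file(stations, destination)


def _cultivar_of(features: pd.DataFrame, registry: CultivarRegistry) -> str:
    cols = [c for c in registry.column_names if c in features.columns]
    if len(cols) != len(registry.column_names):
        raise ValueError("feature table lacks the cultivar indicator block")
    hot = features[cols].iloc[0]
    idx = int(np.argmax(hot.to_numpy()))
    return registry.names[idx]


def gen_lt50_truth(features: pd.DataFrame, config: Lt50GenConfig, seed: int,
                   registry: CultivarRegistry | None = None
                   ) -> tuple[pd.Series, pd.Series]:
    """Deterministic LT50 truth plus a noisy observed series from features.

    Returns ``(truth, observed)``, both indexed like ``features``; observed =
    truth + N(0, noise_sigma).  The truth is a pure function of the feature
    table and the config; only the observation noise consumes the seed.
    """
    registry = registry or CultivarRegistry.default()
    for col in ("chill_cu", "gdh10"):
        if col not in features.columns:
            raise ValueError(f"feature table lacks required column {col!r}")
    cultivar = _cultivar_of(features, registry)
    offset = config.cultivar_offsets.get(registry.species[cultivar], 0.0)

    acclimation = np.minimum(1.0, features["chill_cu"] / config.chill_requirement)
    daily_gdh10 = features["gdh10"].diff()
    daily_gdh10.iloc[0] = features["gdh10"].iloc[0]
    recent_heat = daily_gdh10.ewm(span=config.heat_span_days, adjust=False).mean()

    truth = (
        config.lt50_max_c
        + (config.lt50_min_c - config.lt50_max_c) * acclimation
        + config.deacclimation_gain * recent_heat
        + offset
    ).clip(config.lt50_min_c, config.lt50_max_c)
    truth.name = "lt50_truth_c"

    rng = np.random.default_rng(seed)
    observed = truth + rng.normal(0.0, config.noise_sigma_c, size=len(truth))
    observed.name = "lt50_c"
    return truth, observed
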