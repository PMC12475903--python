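"""Hourly temperature reconstruction and the 126-column predictor scheme.

The cold-hardiness regressor consumes, per station-day-cultivar, a vector of
126 named features built from daily extremes only:

* 4 daily descriptors — tmax, tmin, daily mean ((tmax+tmin)/2), diurnal range;
* 7 cumulative descriptors — Utah, North Carolina and chill-hour (CU)
  chilling accumulations plus growing degree hours at bases 0/4/7/10 C,
  all accumulated hourly from the season start;
* 30 forward and 30 reverse exponentially weighted moving averages of the
  daily mean temperature (spans 1-30 days by default);
* 54 one-hot cultivar indicators;
* days_in_season — days elapsed since the season start date (start day = 0).

Hourly temperatures are reconstructed from daily extremes with an idealized
diurnal curve: a sine rise from the sunrise minimum to an afternoon maximum
equal to the day's tmax, then a logarithmic overnight decline toward the
next sunrise's tmin.  Sunrise and sunset come from standard solar
declination geometry, so the scheme is undefined poleward of the polar
circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .curation import DormantSeason
from .registry import CultivarRegistry

#: Maximum run of consecutive missing days repaired by linear interpolation.
DEFAULT_GAP_LIMIT = 3

#: Growing-degree-hour base temperatures, degrees C.
DEFAULT_GDH_BASES = (0.0, 4.0, 7.0, 10.0)

#: EWMA spans in days (one forward and one reverse feature per span).
DEFAULT_SPANS = tuple(range(1, 31))

DAILY_DESCRIPTORS = ("tmax", "tmin", "tmean", "trange")
CUMULATIVE_DESCRIPTORS = ("chill_utah", "chill_nc", "chill_cu",
                          "gdh0", "gdh4", "gdh7", "gdh10")

#: Utah chilling weights: (upper bound of the temperature interval, weight).
UTAH_TABLE = (
    (1.4, 0.0),
    (2.4, 0.5),
    (9.1, 1.0),
    (12.4, 0.5),
    (15.9, 0.0),
    (18.0, -0.5),
    (math.inf, -1.0),
)

#: North Carolina chilling curve anchors (temperature C, weight); the weight
#: at intermediate temperatures is linearly interpolated, flat outside.
NC_ANCHORS = (
    (1.6, 0.0),
    (7.2, 1.0),
    (13.0, 0.5),
    (16.5, 0.0),
    (19.0, -0.5),
    (20.7, -1.0),
    (23.3, -2.0),
)

#: Chill-hours window (exclusive low, inclusive high), degrees C.
CU_RANGE = (0.0, 7.2)


class GapError(ValueError):
    """A season has a run of missing days too long to interpolate."""


class PolarLatitudeError(ValueError):
    """Diurnal reconstruction undefined where polar day/night occurs."""


@dataclass(frozen=True)
class FeatureConfig:
    spans: tuple[int, ...] = DEFAULT_SPANS
    gdh_bases: tuple[float, ...] = DEFAULT_GDH_BASES
    gap_limit: int = DEFAULT_GAP_LIMIT
    cu_range: tuple[float, float] = CU_RANGE
    utah_table: tuple[tuple[float, float], ...] = UTAH_TABLE
    nc_anchors: tuple[tuple[float, float], ...] = NC_ANCHORS

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.spans):
            raise ValueError("EWMA spans must be >= 1 day")

    @property
    def feature_names(self) -> list[str]:
        """All weather-feature names (everything except the cultivar block)."""
        names = list(DAILY_DESCRIPTORS) + list(CUMULATIVE_DESCRIPTORS)
        names += [f"ewma_{s:02d}" for s in self.spans]
        names += [f"rewma_{s:02d}" for s in self.spans]
        return names


@dataclass
class HourlySeries:
    """24 reconstructed hourly temperatures per day for one station-season."""

    station_id: str
    dates: pd.DatetimeIndex
    temps: np.ndarray  # shape (n_days, 24), degrees C

    def __post_init__(self) -> None:
        if self.temps.shape != (len(self.dates), 24):
            raise ValueError("temps must have shape (n_days, 24)")

    def flat(self) -> np.ndarray:
        return self.temps.reshape(-1)


# ---------------------------------------------------------------------------
# daily gap repair
# ---------------------------------------------------------------------------

def fill_season_gaps(season: DormantSeason,
                     gap_limit: int = DEFAULT_GAP_LIMIT) -> pd.DataFrame:
    """Reindex a season to its full calendar and repair short gaps.

    Runs of up to ``gap_limit`` consecutive missing days are filled by linear
    interpolation (nearest-value at the season edges); any longer run raises
    :class:`GapError` naming the offending date range, even if the season
    passed the day-count screen.
    """
    calendar_ix = pd.date_range(season.start_date, season.end_date,
                                freq="D", inclusive="left")
    frame = season.daily.reindex(calendar_ix)
    frame.index.name = "date"
    for col in ("tmax", "tmin"):
        isna = frame[col].isna().to_numpy()
        if isna.any():
            run_start = None
            for i, flag in enumerate(np.append(isna, False)):
                if flag and run_start is None:
                    run_start = i
                elif not flag and run_start is not None:
                    if i - run_start > gap_limit:
                        raise GapError(
                            f"{season.station_id} season {season.label}: {col} gap "
                            f"{calendar_ix[run_start].date()}.."
                            f"{calendar_ix[i - 1].date()} exceeds {gap_limit} days"
                        )
                    run_start = None
    filled = frame.interpolate(method="linear", limit_direction="both")
    # interpolation can cross the extremes on repaired days; re-order them
    lo = filled[["tmax", "tmin"]].min(axis=1)
    hi = filled[["tmax", "tmin"]].max(axis=1)
    filled["tmax"], filled["tmin"] = hi, lo
    filled["tmean"] = (filled["tmax"] + filled["tmin"]) / 2.0
    filled["trange"] = filled["tmax"] - filled["tmin"]
    return filled


# ---------------------------------------------------------------------------
# solar geometry and the diurnal curve
# ---------------------------------------------------------------------------

def solar_daylength(latitude: float, doy: np.ndarray | int) -> np.ndarray:
    """Day length in hours from solar declination geometry.

    declination = -23.44 deg * cos(2*pi*(doy + 10)/365); the hour angle at
    sunrise satisfies cos(H) = -tan(lat)*tan(decl).
    """
    if abs(latitude) >= 66.6:
        raise PolarLatitudeError(
            f"latitude {latitude}: polar day/night makes the diurnal curve undefined"
        )
    doy = np.asarray(doy, dtype=float)
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0))
    cos_h = -np.tan(np.deg2rad(latitude)) * np.tan(decl)
    cos_h = np.clip(cos_h, -1.0, 1.0)
    return 2.0 * np.rad2deg(np.arccos(cos_h)) / 15.0


def sunrise_sunset(latitude: float, doy: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
    """(sunrise, sunset) in local solar hours, symmetric about solar noon."""
    daylen = solar_daylength(latitude, doy)
    return 12.0 - daylen / 2.0, 12.0 + daylen / 2.0


def hourly_from_daily(season: DormantSeason, latitude: float,
                      gap_limit: int = DEFAULT_GAP_LIMIT) -> HourlySeries:
    """Reconstruct on-the-hour temperatures for a gap-filled season.

    Daytime (sunrise..sunset): T = tmin + (tmax - tmin) * sin(pi * (h - sunrise)
    / (daylength + 4)), peaking at the day's tmax in mid-afternoon.  Night:
    logarithmic decline from the sunset temperature to the next day's sunrise
    minimum.  Each day's sampled maximum is pinned to tmax and the sunrise
    hour to tmin, so daily extremes are recovered exactly.
    """
    filled = fill_season_gaps(season, gap_limit)
    return _hourly_from_filled(filled, season.station_id, latitude)


def _hourly_from_filled(filled: pd.DataFrame, station_id: str,
                        latitude: float) -> HourlySeries:
    dates = filled.index
    doy = dates.dayofyear.to_numpy()
    sunrise, sunset = sunrise_sunset(latitude, doy)
    daylen = sunset - sunrise
    tmax = filled["tmax"].to_numpy()
    tmin = filled["tmin"].to_numpy()
    n = len(dates)
    temps = np.empty((n, 24), dtype=float)
    hours = np.arange(24, dtype=float)

    # temperature at sunset, from the daytime sine
    t_sunset = tmin + (tmax - tmin) * np.sin(np.pi * daylen / (daylen + 4.0))

    for d in range(n):
        day_mask = (hours > sunrise[d]) & (hours <= sunset[d])
        t = np.empty(24)
        t[day_mask] = tmin[d] + (tmax[d] - tmin[d]) * np.sin(
            np.pi * (hours[day_mask] - sunrise[d]) / (daylen[d] + 4.0)
        )
        # morning hours before sunrise: tail of the previous night's decline
        prev = d - 1 if d > 0 else d
        morning = hours <= sunrise[d]
        night_len = 24.0 - sunset[prev] + sunrise[d]
        dt = hours[morning] + 24.0 - sunset[prev]
        t[morning] = t_sunset[prev] - (t_sunset[prev] - tmin[d]) * (
            np.log1p(dt) / np.log1p(night_len)
        )
        # evening hours after sunset: decline toward the next day's minimum
        nxt = d + 1 if d < n - 1 else d
        evening = hours > sunset[d]
        night_len = 24.0 - sunset[d] + sunrise[nxt]
        dt = hours[evening] - sunset[d]
        t[evening] = t_sunset[d] - (t_sunset[d] - tmin[nxt]) * (
            np.log1p(dt) / np.log1p(night_len)
        )
        # pin the sampled extremes to the daily extremes
        peak = int(round(sunrise[d] + (daylen[d] + 4.0) / 2.0))
        t[min(peak, 23)] = tmax[d]
        t[int(round(sunrise[d]))] = tmin[d]
        temps[d] = t

    return HourlySeries(station_id=station_id, dates=dates, temps=temps)


# ---------------------------------------------------------------------------
# hourly accumulations
# ---------------------------------------------------------------------------

def _daily_cumsum(hourly_values: np.ndarray, index: pd.DatetimeIndex) -> pd.Series:
    """Cumulative sum over all hours, reported at the end of each day."""
    per_day = hourly_values.reshape(len(index), 24).sum(axis=1)
    return pd.Series(np.cumsum(per_day), index=index)


def utah_chill(hours: HourlySeries,
               table: Sequence[tuple[float, float]] = UTAH_TABLE) -> pd.Series:
    """Utah-model chill units, accumulated hourly from the season start.

    The stepwise weight table assigns full credit (1.0) between 2.4 and
    9.1 C, half credit on the shoulders, and negative credit above 15.9 C.
    """
    t = hours.temps
    w = np.full(t.shape, next(w for _, w in table if _ == math.inf), dtype=float)
    prev = -math.inf
    for upper, weight in table:
        w[(t > prev) & (t <= upper)] = weight
        prev = upper
    return _daily_cumsum(w, hours.dates)


def nc_chill(hours: HourlySeries,
             anchors: Sequence[tuple[float, float]] = NC_ANCHORS) -> pd.Series:
    """North Carolina model chill units (piecewise-linear weight curve).

    Optimum weight 1.0 at 7.2 C, zero below 1.6 C and at 16.5 C, reaching
    -2.0 at and above 23.3 C.
    """
    xp = np.array([a for a, _ in anchors])
    fp = np.array([w for _, w in anchors])
    w = np.interp(hours.temps, xp, fp, left=fp[0], right=fp[-1])
    return _daily_cumsum(w, hours.dates)


def cu_chill(hours: HourlySeries,
             chill_range: tuple[float, float] = CU_RANGE) -> pd.Series:
    """Chill hours: count of hours with temperature in (low, high] C."""
    lo, hi = chill_range
    w = ((hours.temps > lo) & (hours.temps <= hi)).astype(float)
    return _daily_cumsum(w, hours.dates)


def gdh(hours: HourlySeries, base: float,
        allowed: tuple[float, ...] | None = DEFAULT_GDH_BASES,
        override: bool = False) -> pd.Series:
    """Growing degree hours above ``base``, accumulated from season start.

    GDH = sum over hours of max(0, T - base).  Bases outside the configured
    set are refused unless ``override`` is given.
    """
    if allowed is not None and base not in allowed and not override:
        raise ValueError(
            f"GDH base {base} not in configured set {allowed}; pass override=True"
        )
    w = np.maximum(0.0, hours.temps - base)
    return _daily_cumsum(w, hours.dates)


# ---------------------------------------------------------------------------
# exponentially weighted moving averages
# ---------------------------------------------------------------------------

def ewma_features(daily_mean: Sequence[float] | pd.Series,
                  spans: Sequence[int] = DEFAULT_SPANS) -> pd.DataFrame:
    """Forward EWMAs of the daily mean, one column per span.

    Recursive form with alpha = 2/(span+1), initialized at the first value
    (adjust=False convention).
    """
    if any(s < 1 for s in spans):
        raise ValueError("EWMA spans must be >= 1")
    series = pd.Series(daily_mean, dtype=float)
    out = {f"ewma_{s:02d}": series.ewm(span=s, adjust=False).mean() for s in spans}
    frame = pd.DataFrame(out)
    if isinstance(daily_mean, pd.Series):
        frame.index = daily_mean.index
    return frame


def reverse_ewma_features(daily_mean: Sequence[float] | pd.Series,
                          spans: Sequence[int] = DEFAULT_SPANS) -> pd.DataFrame:
    """Reverse EWMAs: the season-to-date prefix traversed current-day -> start.

    For day t the value is the recursive EWMA of (x_t, x_{t-1}, ..., x_0)
    evaluated at x_0, putting the greatest weight on the earliest days:

        r_t = alpha * sum_{j<t} (1-alpha)^j x_j + (1-alpha)^t x_t

    computed here with an O(n) prefix recursion per span.
    """
    if any(s < 1 for s in spans):
        raise ValueError("EWMA spans must be >= 1")
    x = np.asarray(daily_mean, dtype=float)
    n = len(x)
    out = {}
    j = np.arange(n, dtype=float)
    for s in spans:
        alpha = 2.0 / (s + 1.0)
        decay = np.power(1.0 - alpha, j)
        prefix = np.concatenate(([0.0], np.cumsum(decay[:-1] * x[:-1]))) if n else np.array([])
        out[f"rewma_{s:02d}"] = alpha * prefix + decay * x
    frame = pd.DataFrame(out)
    if isinstance(daily_mean, pd.Series):
        frame.index = daily_mean.index
    return frame


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_features(season: DormantSeason, latitude: float, cultivar: str,
                      registry: CultivarRegistry | None = None,
                      config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Emit the full 126-column predictor table for one season and cultivar.

    Index: the season's calendar dates.  Columns: 4 daily descriptors, 7
    cumulative descriptors, the forward and reverse EWMA blocks, the 54
    cultivar indicators and ``days_in_season``.  The column-count identity
    4 + 7 + 30 + 30 + 54 + 1 = 126 is asserted structurally on every call.
    """
    registry = registry or CultivarRegistry.default()
    filled = fill_season_gaps(season, config.gap_limit)
    hourly = _hourly_from_filled(filled, season.station_id, latitude)

    frame = filled[list(DAILY_DESCRIPTORS)].copy()
    frame["chill_utah"] = utah_chill(hourly, config.utah_table)
    frame["chill_nc"] = nc_chill(hourly, config.nc_anchors)
    frame["chill_cu"] = cu_chill(hourly, config.cu_range)
    for base in config.gdh_bases:
        frame[f"gdh{base:g}"] = gdh(hourly, base, config.gdh_bases)

    frame = pd.concat(
        [frame,
         ewma_features(filled["tmean"], config.spans),
         reverse_ewma_features(filled["tmean"], config.spans)],
        axis=1,
    )

    onehot = registry.one_hot(cultivar)
    for col, val in onehot.items():
        frame[col] = val
    frame["days_in_season"] = (frame.index - season.start_date).days

    expected = (len(DAILY_DESCRIPTORS) + len(CUMULATIVE_DESCRIPTORS)
                + 2 * len(config.spans) + len(registry.names) + 1)
    if frame.shape[1] != expected:
        raise AssertionError(
            f"feature count {frame.shape[1]} != expected {expected}"
        )
    return frame


def feature_columns(registry: CultivarRegistry | None = None,
                    config: FeatureConfig = FeatureConfig()) -> list[str]:
    """The canonical ordered list of predictor column names."""
    registry = registry or CultivarRegistry.default()
    return config.feature_names + registry.column_names + ["days_in_season"]
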