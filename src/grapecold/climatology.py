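"""Seasonal summaries, multi-decade windows, KNN gridding and feasible area.

The climatology layer condenses daily LT50/damage series into one row per
station and dormant season (seasonal minimum temperature, deepest hardiness,
maximum damage potential), averages those rows over multi-decade windows
(default 1960-1979, 1980-1999, 2000-2024), spreads the station values onto a
regular latitude/longitude grid with k-nearest-neighbour averaging under
great-circle distance, and reports the share of grid area whose damage stays
below a feasibility threshold (default 20%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curation import DormantSeason
from .hardiness import damage_potential

EARTH_RADIUS_KM = 6371.0

DEFAULT_WINDOWS = {
    "1960-1979": (1960, 1979),
    "1980-1999": (1980, 1999),
    "2000-2024": (2000, 2024),
}

DEFAULT_K = 5
DEFAULT_RESOLUTION = 0.5
DEFAULT_FEASIBLE_THRESHOLD = 20.0


@dataclass(frozen=True)
class SeasonSummary:
    """Per-season extremes at one station for one cultivar (or 'all')."""

    station_id: str
    season_label: int
    cultivar: str
    min_temperature: float  # seasonal minimum tmin, degrees C
    max_hardiness: float    # deepest hardiness = most negative LT50, degrees C
    max_damage: float       # maximum daily damage potential, 0-100


@dataclass(frozen=True)
class GridSpec:
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = DEFAULT_RESOLUTION

    def cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (lat, lon) coordinates of all grid-cell centres."""
        lats = np.arange(self.lat_min, self.lat_max + 1e-9, self.resolution)
        lons = np.arange(self.lon_min, self.lon_max + 1e-9, self.resolution)
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        return glat.ravel(), glon.ravel()


def season_summary(lt50: pd.Series, season: DormantSeason,
                   cultivar: str = "all") -> SeasonSummary:
    """Condense one season's daily LT50 series into its seasonal extremes.

    ``lt50`` is indexed by date and must overlap the season's recorded days;
    damage is evaluated day-by-day against the same day's minimum
    temperature.
    """
    tmin = season.daily["tmin"].dropna()
    joint = pd.concat({"lt50": lt50, "tmin": tmin}, axis=1, join="inner").dropna()
    if joint.empty:
        raise ValueError(
            f"{season.station_id} season {season.label}: no overlapping dates "
            "between LT50 series and season record"
        )
    daily_damage = damage_potential(joint["tmin"], joint["lt50"])
    return SeasonSummary(
        station_id=season.station_id,
        season_label=season.label,
        cultivar=cultivar,
        min_temperature=float(joint["tmin"].min()),
        max_hardiness=float(joint["lt50"].min()),
        max_damage=float(np.max(daily_damage)),
    )


def summaries_frame(summaries: list[SeasonSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def window_average(summaries: pd.DataFrame,
                   windows: dict[str, tuple[int, int]] = DEFAULT_WINDOWS
                   ) -> pd.DataFrame:
    """Mean seasonal extremes per station per window.

    ``summaries`` must carry columns station_id, season_label, and the
    numeric summary fields.  Windows are inclusive year ranges and must not
    overlap; a station with no seasons in a window is omitted from it.
    """
    spans = sorted(windows.items(), key=lambda kv: kv[1])
    for (_, a), (_, b) in zip(spans, spans[1:]):
        if a[1] >= b[0]:
            raise ValueError(f"windows {a} and {b} overlap")

    def to_window(label: int) -> str | None:
        for name, (y0, y1) in windows.items():
            if y0 <= label <= y1:
                return name
        return None

    frame = summaries.copy()
    frame["window"] = frame["season_label"].map(to_window)
    frame = frame.dropna(subset=["window"])
    value_cols = [c for c in ("min_temperature", "max_hardiness", "max_damage")
                  if c in frame.columns]
    group_cols = ["station_id", "window"]
    if "cultivar" in frame.columns:
        group_cols.insert(1, "cultivar")
    out = frame.groupby(group_cols, as_index=False)[value_cols].mean()
    out["n_seasons"] = frame.groupby(group_cols).size().to_numpy()
    return out


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in kilometres (elementwise / broadcasting)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float),
                                              np.asarray(lon1, float),
                                              np.asarray(lat2, float),
                                              np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def knn_grid(stations: pd.DataFrame, grid: GridSpec,
             k: int = DEFAULT_K) -> pd.DataFrame:
    """Average the k nearest stations' values onto each grid cell.

    ``stations`` needs columns latitude, longitude, value.  Distance is
    great-circle; ties are broken by station row order, so the estimate is
    fully deterministic.  Every cell value is a convex combination (an
    unweighted mean) of station values.
    """
    n = len(stations)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available stations")
    glat, glon = grid.cells()
    slat = stations["latitude"].to_numpy()
    slon = stations["longitude"].to_numpy()
    values = stations["value"].to_numpy(dtype=float)
    # (cells, stations) distance matrix; fine at the grid sizes used here
    dist = haversine_km(glat[:, None], glon[:, None], slat[None, :], slon[None, :])
    order = np.lexsort((np.broadcast_to(np.arange(n), dist.shape), dist), axis=1)
    nearest = order[:, :k]
    cell_values = values[nearest].mean(axis=1)
    return pd.DataFrame({"latitude": glat, "longitude": glon, "value": cell_values})


def feasible_fraction(grid_values: pd.DataFrame,
                      threshold: float = DEFAULT_FEASIBLE_THRESHOLD) -> float:
    """Area-weighted share of grid cells with damage below ``threshold``.

    Cell area is weighted by cos(latitude); no land/sea mask is applied.
    """
    lat = grid_values["latitude"].to_numpy(dtype=float)
    val = grid_values["value"].to_numpy(dtype=float)
    weights = np.cos(np.radians(lat))
    return float(np.sum(weights * (val < threshold)) / np.sum(weights))


def feasible_area(grids: dict[str, pd.DataFrame], baseline: str,
                  threshold: float = DEFAULT_FEASIBLE_THRESHOLD) -> pd.DataFrame:
    """Feasible fraction per window and percent change versus a baseline.

    Change = 100 * (F_window - F_baseline) / F_baseline; undefined (NaN)
    when the baseline fraction is zero.
    """
    if baseline not in grids:
        raise ValueError(f"baseline window {baseline!r} not among {sorted(grids)}")
    fractions = {name: feasible_fraction(g, threshold) for name, g in grids.items()}
    base = fractions[baseline]
    rows = []
    for name, frac in fractions.items():
        change = 100.0 * (frac - base) / base if base > 0 else float("nan")
        rows.append({"window": name, "feasible_fraction": frac,
                     "pct_change_vs_baseline": change})
    return pd.DataFrame(rows)
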