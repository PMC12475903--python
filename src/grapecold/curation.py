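"""Station curation: filtering of daily records and dormant-season segmentation.

Four screens are applied to each station before any cold-hardiness modelling:

* geographic  — keep stations with 30 deg <= |latitude| <= 55 deg (both
  hemispheres; the band covers current and climate-shifted viticulture);
* temporal    — discard all data before 1960-01-01 and stations that ceased
  recording before then;
* record type — keep stations whose post-cutoff record has daily maximum AND
  minimum temperatures spanning at least two years (730 days);
* quality     — segment the record into dormant seasons (1 Sep - 1 May in the
  northern hemisphere, 1 Mar - 1 Nov in the southern) and keep only seasons
  with at least 220 days on which both extremes were recorded.

The record-length screen is evaluated on the post-cutoff record so that the
whole pipeline is idempotent: re-curating curated output changes nothing.
Season windows are closed at the start date and open at the end date, giving
242-243 candidate days in the north.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .ghcnd import DailySeries, StationMeta

logger = logging.getLogger(__name__)

#: Days per "year of data" in the record-length screen.
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class CurationConfig:
    latitude_band: tuple[float, float] = (30.0, 55.0)
    min_station_years: int = 2
    temporal_cutoff: date = date(1960, 1, 1)
    min_season_days: int = 220

    def __post_init__(self) -> None:
        lo, hi = self.latitude_band
        if not 0.0 < lo < hi <= 90.0:
            raise ValueError(f"latitude band must satisfy 0 < low < high <= 90, got {self.latitude_band}")
        if self.min_season_days > 243:
            raise ValueError("min_season_days cannot exceed the longest season span (243)")
        if self.min_station_years < 0:
            raise ValueError("min_station_years must be non-negative")


@dataclass
class DormantSeason:
    """One hemisphere-aware dormant-season slice of a station's daily record."""

    station_id: str
    hemisphere: str  # "N" or "S"
    label: int  # calendar year containing the season start
    start_date: pd.Timestamp
    end_date: pd.Timestamp  # exclusive
    daily: pd.DataFrame = field(repr=False)

    @property
    def days_recorded(self) -> int:
        """Number of in-season dates with both tmax and tmin present."""
        both = self.daily["tmax"].notna() & self.daily["tmin"].notna()
        return int(both.sum())

    @property
    def span_days(self) -> int:
        return int((self.end_date - self.start_date).days)


def filter_geographic(meta: StationMeta,
                      band: tuple[float, float] = (30.0, 55.0)) -> bool:
    """Keep a station iff band_low <= |latitude| <= band_high (inclusive)."""
    lo, hi = band
    return lo <= abs(meta.latitude) <= hi


def filter_temporal(series: DailySeries, cutoff: date = date(1960, 1, 1)) -> DailySeries | None:
    """Drop all records dated before ``cutoff``; None if nothing remains."""
    cut = pd.Timestamp(cutoff)
    frame = series.data.loc[series.data.index >= cut]
    if frame.empty:
        return None
    return DailySeries(station_id=series.station_id, data=frame)


def filter_record_type(series: DailySeries,
                       min_station_years: int = 2) -> tuple[bool, str | None]:
    """Screen on record type and length.

    Drops a station that has no date with both extremes present, or whose
    first-to-last dual-extreme span is shorter than ``min_station_years``
    years (365 days per year).
    """
    dual = series.dual_dates
    if len(dual) == 0:
        return False, "no records"
    span = (dual[-1] - dual[0]).days
    if span < min_station_years * DAYS_PER_YEAR:
        return False, "record shorter than %d years" % min_station_years
    return True, None


def _season_window(year: int, hemisphere: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    if hemisphere == "N":
        return pd.Timestamp(year=year, month=9, day=1), pd.Timestamp(year=year + 1, month=5, day=1)
    return pd.Timestamp(year=year, month=3, day=1), pd.Timestamp(year=year, month=11, day=1)


def segment_seasons(series: DailySeries, meta: StationMeta) -> list[DormantSeason]:
    """Slice a daily record into dormant seasons for the station's hemisphere.

    A season is emitted for every start year with at least one record inside
    the window [start, end).  The season label is the calendar year of the
    start date.
    """
    if meta.latitude == 0.0:
        raise ValueError(
            f"station {meta.station_id}: hemisphere undefined at latitude 0"
        )
    hemisphere = "N" if meta.latitude > 0 else "S"
    frame = series.data
    if frame.empty:
        return []
    first_year = frame.index[0].year - 1
    last_year = frame.index[-1].year
    seasons: list[DormantSeason] = []
    for year in range(first_year, last_year + 1):
        start, end = _season_window(year, hemisphere)
        sl = frame.loc[(frame.index >= start) & (frame.index < end)]
        if sl.empty:
            continue
        seasons.append(
            DormantSeason(
                station_id=series.station_id,
                hemisphere=hemisphere,
                label=year,
                start_date=start,
                end_date=end,
                daily=sl,
            )
        )
    return seasons


def filter_quality(season: DormantSeason, min_season_days: int = 220) -> bool:
    """Keep a season iff it has at least ``min_season_days`` dual-extreme days."""
    return season.days_recorded >= min_season_days


@dataclass
class CurationResult:
    """Outcome of curating a station network."""

    seasons: list[DormantSeason]
    series: dict[str, DailySeries]  # post-cutoff record of each kept station
    stations: dict[str, StationMeta]
    report: pd.DataFrame


def curate(inventory: list[StationMeta],
           series_by_station: dict[str, DailySeries],
           config: CurationConfig = CurationConfig()) -> CurationResult:
    """Run the full curation pipeline over a station network.

    Returns the kept dormant seasons, the kept stations' post-cutoff daily
    series, and a per-station report with the filters failed, seasons kept,
    record length in years and number of seasons dropped for missing data.
    """
    rows = []
    kept_seasons: list[DormantSeason] = []
    kept_series: dict[str, DailySeries] = {}
    kept_meta: dict[str, StationMeta] = {}
    for meta in inventory:
        sid = meta.station_id
        failed: list[str] = []
        n_kept = 0
        n_missing = 0
        record_years = 0.0
        series = series_by_station.get(sid)
        if series is None:
            failed.append("no records")
        elif not filter_geographic(meta, config.latitude_band):
            failed.append("geographic")
        else:
            truncated = filter_temporal(series, config.temporal_cutoff)
            if truncated is None:
                failed.append("temporal")
            else:
                ok, reason = filter_record_type(truncated, config.min_station_years)
                dual = truncated.dual_dates
                if len(dual):
                    record_years = (dual[-1] - dual[0]).days / DAYS_PER_YEAR
                if not ok:
                    failed.append(f"record type ({reason})")
                else:
                    seasons = segment_seasons(truncated, meta)
                    for season in seasons:
                        if filter_quality(season, config.min_season_days):
                            kept_seasons.append(season)
                            n_kept += 1
                        else:
                            n_missing += 1
                    if n_kept == 0:
                        failed.append("quality (no season with enough days)")
                    else:
                        kept_series[sid] = truncated
                        kept_meta[sid] = meta
        rows.append(
            {
                "station_id": sid,
                "kept": not failed,
                "filters_failed": ";".join(failed),
                "seasons_kept": n_kept if not failed else 0,
                "record_years": round(record_years, 2),
                "missing_seasons": n_missing,
            }
        )
        if failed:
            logger.info("station %s dropped: %s", sid, "; ".join(failed))
    # a station that failed outright contributes no seasons
    kept_seasons = [s for s in kept_seasons if s.station_id in kept_series]
    report = pd.DataFrame(rows)
    return CurationResult(
        seasons=kept_seasons, series=kept_series, stations=kept_meta, report=report
    )
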