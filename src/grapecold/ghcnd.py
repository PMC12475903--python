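"""Reading and writing GHCNd fixed-width daily files and station inventories.

The GHCNd archive stores one element (TMAX, TMIN, PRCP, ...) per line in a
269-character fixed-width layout: station id in columns 1-11, year 12-15,
month 16-17, element 18-21, then 31 repeating groups of value (5 chars,
tenths of a degree Celsius for temperature elements) plus three one-character
flags (measurement, quality, source).  This module decodes TMAX/TMIN into a
per-station daily series in plain degrees Celsius and parses the companion
``ghcnd-stations.txt`` inventory.  The tenths encoding exists only at the
file boundary; everything downstream works in degrees C.
"""

from __future__ import annotations

import calendar
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: GHCNd sentinel for a missing element value.
MISSING_VALUE = -9999

#: Plausibility bounds for a decoded air temperature, degrees C.
TEMP_BOUNDS = (-90.0, 70.0)

_LINE_LEN = 269
_ELEMENTS = ("TMAX", "TMIN")


class GhcndParseError(ValueError):
    """Raised when a .dly or station-inventory line cannot be decoded."""


@dataclass(frozen=True)
class StationMeta:
    """One row of the GHCNd station inventory."""

    station_id: str
    latitude: float
    longitude: float
    elevation: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.station_id:
            raise ValueError("station_id must be non-empty")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"station {self.station_id}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(
                f"station {self.station_id}: longitude {self.longitude} outside [-180, 180]"
            )


@dataclass
class DailySeries:
    """Daily TMAX/TMIN record for one station, degrees C with NaN for missing.

    ``data`` is indexed by a strictly increasing DatetimeIndex named ``date``
    and carries float columns ``tmax`` and ``tmin``.  Whenever both are
    present on a date, tmax >= tmin (physically inconsistent days are blanked
    at parse time).
    """

    station_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("DailySeries.data must have a DatetimeIndex")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("DailySeries dates must be strictly increasing")
        missing = {"tmax", "tmin"} - set(self.data.columns)
        if missing:
            raise ValueError(f"DailySeries.data lacks columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dual_dates(self) -> pd.DatetimeIndex:
        """Dates on which both tmax and tmin are present."""
        both = self.data["tmax"].notna() & self.data["tmin"].notna()
        return self.data.index[both]


def _open(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_dly(source: str | Path | TextIO) -> DailySeries:
    """Parse one station's GHCNd ``.dly`` stream into a :class:`DailySeries`.

    Only TMAX and TMIN lines are decoded; other elements are ignored.  A
    value of -9999, any non-blank quality flag, or a decoded temperature
    outside the plausibility bounds yields a missing day.  Days beyond the
    calendar length of a month are skipped.  Mixing station ids in one
    stream is an error.
    """
    stream, close = _open(source)
    records: dict[pd.Timestamp, dict[str, float]] = {}
    station_id: str | None = None
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if len(line) != _LINE_LEN:
                raise GhcndParseError(
                    f"line {lineno}: expected {_LINE_LEN} characters, got {len(line)}"
                )
            sid = line[0:11]
            if station_id is None:
                station_id = sid
            elif sid != station_id:
                raise GhcndParseError(
                    f"line {lineno}: mixed station ids {station_id!r} and {sid!r}"
                )
            element = line[17:21]
            if element not in _ELEMENTS:
                continue
            try:
                year = int(line[11:15])
                month = int(line[15:17])
            except ValueError as exc:
                raise GhcndParseError(f"line {lineno}: bad year/month field") from exc
            if not 1 <= month <= 12:
                raise GhcndParseError(f"line {lineno}: month {month} out of range")
            ndays = calendar.monthrange(year, month)[1]
            for day in range(31):
                off = 21 + 8 * day
                value_str = line[off : off + 5]
                qflag = line[off + 6]
                if day >= ndays:
                    continue
                try:
                    value = int(value_str)
                except ValueError as exc:
                    raise GhcndParseError(
                        f"line {lineno}: non-numeric value field {value_str!r}"
                    ) from exc
                date = pd.Timestamp(year=year, month=month, day=day + 1)
                cell = records.setdefault(date, {})
                if value == MISSING_VALUE or qflag != " ":
                    cell.setdefault(element.lower(), np.nan)
                    continue
                temp = value * 0.1
                if not TEMP_BOUNDS[0] <= temp <= TEMP_BOUNDS[1]:
                    logger.warning(
                        "%s %s %s: %.1f C outside plausibility bounds, set missing",
                        sid, date.date(), element, temp,
                    )
                    temp = np.nan
                cell[element.lower()] = temp
    finally:
        if close:
            stream.close()

    if station_id is None:
        raise GhcndParseError("empty .dly stream")

    frame = pd.DataFrame.from_dict(records, orient="index").reindex(
        columns=["tmax", "tmin"]
    )
    frame.index.name = "date"
    frame = frame.sort_index().astype(float)

    bad = frame["tmax"].notna() & frame["tmin"].notna() & (frame["tmax"] < frame["tmin"])
    if bad.any():
        logger.warning(
            "%s: %d day(s) with tmax < tmin blanked", station_id, int(bad.sum())
        )
        frame.loc[bad, ["tmax", "tmin"]] = np.nan
    return DailySeries(station_id=station_id, data=frame)


def write_dly(series: DailySeries, destination: str | Path | TextIO) -> None:
    """Encode a DailySeries back into the GHCNd fixed-width dialect.

    Inverse of :func:`read_dly` up to the 0.1 C encoding resolution; flags
    are written blank.
    """
    stream, close = _open_w(destination)
    try:
        frame = series.data
        periods = sorted({(d.year, d.month) for d in frame.index})
        for year, month in periods:
            ndays = calendar.monthrange(year, month)[1]
            month_dates = pd.date_range(
                f"{year}-{month:02d}-01", periods=ndays, freq="D"
            )
            for element in _ELEMENTS:
                col = frame[element.lower()].reindex(month_dates)
                if col.isna().all() and not any(d in frame.index for d in month_dates):
                    continue
                parts = [f"{series.station_id:<11.11}{year:04d}{month:02d}{element}"]
                for day in range(31):
                    if day < ndays and pd.notna(col.iloc[day]):
                        value = int(round(col.iloc[day] * 10.0))
                    else:
                        value = MISSING_VALUE
                    parts.append(f"{value:5d}   ")
                stream.write("".join(parts) + "\n")
    finally:
        if close:
            stream.close()


def _open_w(destination: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(destination, (str, Path)):
        return open(destination, "w", encoding="utf-8"), True
    return destination, False


def read_station_file(source: str | Path | TextIO) -> list[StationMeta]:
    """Parse a ``ghcnd-stations.txt`` fixed-width inventory.

    Columns: id 1-11, latitude 13-20, longitude 22-30, elevation 32-37
    (-999.9 means missing), name 42-71.  Duplicate ids or out-of-range
    coordinates are errors.
    """
    stream, close = _open(source)
    stations: list[StationMeta] = []
    seen: set[str] = set()
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            sid = line[0:11].strip()
            try:
                lat = float(line[12:20])
                lon = float(line[21:30])
                elev = float(line[31:37])
            except ValueError as exc:
                raise GhcndParseError(
                    f"line {lineno}: bad numeric field in station inventory"
                ) from exc
            if sid in seen:
                raise GhcndParseError(f"line {lineno}: duplicate station id {sid!r}")
            seen.add(sid)
            name = line[41:71].strip() if len(line) > 41 else ""
            try:
                meta = StationMeta(
                    station_id=sid,
                    latitude=lat,
                    longitude=lon,
                    elevation=None if elev == -999.9 else elev,
                    name=name,
                )
            except ValueError as exc:
                raise GhcndParseError(str(exc)) from exc
            stations.append(meta)
    finally:
        if close:
            stream.close()
    return stations


def write_station_file(stations: Iterable[StationMeta],
                       destination: str | Path | TextIO) -> None:
    """Write stations in the ghcnd-stations fixed-width dialect."""
    stream, close = _open_w(destination)
    try:
        for st in stations:
            elev = -999.9 if st.elevation is None else st.elevation
            stream.write(
                f"{st.station_id:<11.11} {st.latitude:8.4f} {st.longitude:9.4f} "
                f"{elev:6.1f}    {st.name:<30.30}\n"
            )
    finally:
        if close:
            stream.close()


def write_table(records: pd.DataFrame, destination: str | Path | TextIO,
                index: bool = False) -> None:
    """Write a tabular result as comma-delimited UTF-8 with a header row.

    NaN cells become empty fields; round-trips through :func:`read_table`.
    """
    records.to_csv(destination, index=index)


def read_table(source: str | Path | TextIO, **kwargs) -> pd.DataFrame:
    """Read a delimited table written by :func:`write_table`."""
    return pd.read_csv(source, **kwargs)
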