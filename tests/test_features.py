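"""Diurnal reconstruction, chill/heat accumulators, EWMAs and assembly."""

import numpy as np
import pandas as pd
import pytest

from grapecold.curation import DormantSeason
from grapecold.features import (
    CUMULATIVE_DESCRIPTORS,
    DAILY_DESCRIPTORS,
    FeatureConfig,
    GapError,
    HourlySeries,
    PolarLatitudeError,
    assemble_features,
    cu_chill,
    ewma_features,
    fill_season_gaps,
    gdh,
    hourly_from_daily,
    nc_chill,
    reverse_ewma_features,
    sunrise_sunset,
    utah_chill,
)


def _season(tmax=10.0, tmin=0.0, days=None, start="1990-09-01", end="1991-05-01"):
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    ix = pd.date_range(start, end, freq="D", inclusive="left")
    frame = pd.DataFrame({"tmax": tmax, "tmin": tmin}, index=ix)
    if days is not None:
        frame = frame.iloc[:days]
    return DormantSeason(station_id="TEST0000001", hemisphere="N", label=1990,
                         start_date=start, end_date=end, daily=frame)


def _hours(temps_per_day, days=1, start="1990-09-01"):
    """HourlySeries with the same 24 hourly values every day."""
    dates = pd.date_range(start, periods=days, freq="D")
    temps = np.tile(np.asarray(temps_per_day, dtype=float), (days, 1))
    return HourlySeries(station_id="T", dates=dates, temps=temps)


class TestHourlyReconstruction:
    def test_flat_day_gives_flat_hours(self):
        season = _season(tmax=10.0, tmin=10.0)
        hourly = hourly_from_daily(season, latitude=45.0)
        assert np.allclose(hourly.temps, 10.0)

    def test_each_day_max_is_tmax_and_min_respects_tmin(self):
        season = _season(tmax=12.0, tmin=-3.0)
        hourly = hourly_from_daily(season, latitude=45.0)
        assert np.allclose(hourly.temps.max(axis=1), 12.0)
        assert hourly.temps.min() >= -3.0 - 1e-9

    def test_equinox_day_length_near_12h(self):
        # spring equinox: day of year ~81
        sr, ss = sunrise_sunset(45.0, 81)
        assert ss - sr == pytest.approx(12.0, abs=0.25)  # within 15 min

    def test_polar_latitude_rejected(self):
        with pytest.raises(PolarLatitudeError):
            hourly_from_daily(_season(), latitude=70.0)

    def test_long_gap_is_an_error_naming_dates(self):
        season = _season()
        season.daily.iloc[40:46, :] = np.nan  # 6-day gap
        with pytest.raises(GapError, match="1990-10-1"):
            hourly_from_daily(season, latitude=45.0)

    def test_short_gap_interpolated(self):
        season = _season(tmax=10.0, tmin=0.0)
        season.daily.iloc[40:43, :] = np.nan
        filled = fill_season_gaps(season)
        assert not filled[["tmax", "tmin"]].isna().any().any()
        assert filled["tmax"].iloc[41] == pytest.approx(10.0)


class TestChillModels:
    @pytest.mark.parametrize("temp, expected", [
        (5.0, 1.0), (20.0, -1.0), (1.0, 0.0), (2.0, 0.5), (10.0, 0.5),
        (14.0, 0.0), (17.0, -0.5),
    ])
    def test_utah_weight_table(self, temp, expected):
        total = utah_chill(_hours([temp] * 24)).iloc[-1]
        assert total == pytest.approx(24 * expected)

    def test_utah_negative_day(self):
        assert utah_chill(_hours([20.0] * 24)).iloc[-1] == pytest.approx(-24.0)

    @pytest.mark.parametrize("temp, check", [
        (7.2, lambda v: v == pytest.approx(1.0)),
        (25.0, lambda v: v < 0.0),
        (0.0, lambda v: v == pytest.approx(0.0)),
    ])
    def test_nc_curve_shape(self, temp, check):
        per_hour = nc_chill(_hours([temp] * 24)).iloc[-1] / 24.0
        assert check(per_hour)

    def test_nc_accumulates_over_days(self):
        total = nc_chill(_hours([7.2] * 24, days=10)).iloc[-1]
        assert total == pytest.approx(240.0)

    @pytest.mark.parametrize("temp, expected", [(5.0, 1.0), (-2.0, 0.0),
                                                (7.2, 1.0), (7.3, 0.0), (0.0, 0.0)])
    def test_cu_chill_hour_window(self, temp, expected):
        # one in-range candidate hour, the other 23 far below the window
        day = [temp] + [-10.0] * 23
        assert cu_chill(_hours(day)).iloc[-1] == pytest.approx(expected)

    def test_cu_chill_accumulation(self):
        assert cu_chill(_hours([4.0] * 24, days=2)).iloc[-1] == pytest.approx(48.0)


class TestGdh:
    @pytest.mark.parametrize("base, expected", [(4.0, 144.0), (10.0, 0.0),
                                                (0.0, 240.0)])
    def test_constant_day(self, base, expected):
        assert gdh(_hours([10.0] * 24), base).iloc[-1] == pytest.approx(expected)

    def test_unconfigured_base_rejected_unless_overridden(self):
        hours = _hours([10.0] * 24)
        with pytest.raises(ValueError, match="base"):
            gdh(hours, 5.0)
        assert gdh(hours, 5.0, override=True).iloc[-1] == pytest.approx(120.0)

    def test_base_ordering_on_random_hours(self, rng):
        temps = rng.uniform(-20, 30, size=(30, 24))
        hours = HourlySeries("T", pd.date_range("1990-09-01", periods=30), temps)
        g = {b: gdh(hours, b).iloc[-1] for b in (0.0, 4.0, 7.0, 10.0)}
        assert g[0.0] >= g[4.0] >= g[7.0] >= g[10.0] >= 0.0


class TestEwma:
    def test_constant_series_fixed_point_all_spans(self):
        fwd = ewma_features([5.0] * 40)
        rev = reverse_ewma_features([5.0] * 40)
        assert np.allclose(fwd.to_numpy(), 5.0)
        assert np.allclose(rev.to_numpy(), 5.0)

    def test_one_step_recurrence(self):
        # span 3 -> alpha 0.5; EWMA after (0, 10) is 5.0
        fwd = ewma_features([0.0, 10.0], spans=[3])
        assert fwd.iloc[-1, 0] == pytest.approx(5.0)

    def test_span_one_is_identity(self):
        x = [1.0, -4.0, 7.5]
        fwd = ewma_features(x, spans=[1])
        assert np.allclose(fwd.to_numpy().ravel(), x)

    def test_reverse_span_one_picks_season_start(self):
        rev = reverse_ewma_features([0.0, 10.0], spans=[1])
        assert rev.iloc[-1, 0] == pytest.approx(0.0)

    def test_matches_explicit_weight_oracle(self, rng):
        """Both EWMA directions equal brute-force weighted sums, all 30 spans."""
        x = rng.normal(0.0, 10.0, size=60)
        spans = list(range(1, 31))
        fwd = ewma_features(x, spans)
        rev = reverse_ewma_features(x, spans)
        for s in spans:
            alpha = 2.0 / (s + 1.0)
            for t in (0, 1, 7, 31, 59):
                # forward: weights alpha*(1-alpha)^(t-j) on x_j, remainder on x_0
                w = np.array([alpha * (1 - alpha) ** (t - j) for j in range(t + 1)])
                w[0] = (1 - alpha) ** t
                assert fwd.iloc[t, s - 1] == pytest.approx(np.dot(w, x[:t + 1]))
                # reverse: same weights applied to the reversed prefix
                assert rev.iloc[t, s - 1] == pytest.approx(np.dot(w, x[t::-1]))

    def test_bounded_by_running_extremes(self, rng):
        x = rng.normal(0.0, 5.0, size=100)
        run_min, run_max = np.minimum.accumulate(x), np.maximum.accumulate(x)
        for frame in (ewma_features(x), reverse_ewma_features(x)):
            vals = frame.to_numpy()
            assert (vals >= run_min[:, None] - 1e-9).all()
            assert (vals <= run_max[:, None] + 1e-9).all()

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            ewma_features([1.0], spans=[0])
        with pytest.raises(ValueError):
            reverse_ewma_features([1.0], spans=[0])


class TestAssembly:
    def test_exactly_126_named_features(self, feature_table):
        assert feature_table.shape[1] == 126

    def test_block_decomposition(self, feature_table, registry):
        cols = list(feature_table.columns)
        assert cols[:4] == list(DAILY_DESCRIPTORS)
        assert cols[4:11] == list(CUMULATIVE_DESCRIPTORS)
        assert sum(c.startswith("ewma_") for c in cols) == 30
        assert sum(c.startswith("rewma_") for c in cols) == 30
        assert sum(c.startswith("cv_") for c in cols) == 54
        assert cols[-1] == "days_in_season"

    def test_cultivar_indicators_one_hot(self, feature_table):
        onehot = feature_table.filter(like="cv_")
        assert set(np.unique(onehot.to_numpy())) <= {0.0, 1.0}
        assert (onehot.sum(axis=1) == 1.0).all()
        assert (feature_table["cv_riesling"] == 1.0).all()

    def test_days_in_season_anchored_at_start(self, feature_table):
        assert feature_table["days_in_season"].iloc[0] == 0
        assert feature_table.loc["2000-10-01", "days_in_season"] == 30

    def test_unknown_cultivar_lists_registry(self, quality_season, registry,
                                             weather_station):
        meta, _ = weather_station
        with pytest.raises(KeyError, match="Riesling"):
            assemble_features(quality_season, meta.latitude, "Pinotage", registry)

    def test_chill_monotonicity(self, feature_table):
        # CU chill-hours count never decreases; GDH columns never decrease
        for col in ("chill_cu", "gdh0", "gdh4", "gdh7", "gdh10"):
            assert (feature_table[col].diff().dropna() >= -1e-9).all(), col

    def test_registry_wrong_size_rejected(self):
        from grapecold.registry import CultivarRegistry
        with pytest.raises(ValueError, match="54"):
            CultivarRegistry(names=("A", "B"), species={"A": "hybrid", "B": "hybrid"})
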