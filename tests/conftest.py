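"""Shared fixtures: synthetic stations, seasons and a training-scale dataset.

Everything is generated programmatically from fixed seeds; nothing is read
from disk.  The expensive fixtures (feature tables, the ~2900-row training
set) are session-scoped so the regression and recovery tests share them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from grapecold import (
    CultivarRegistry,
    Lt50GenConfig,
    WeatherGenConfig,
    assemble_features,
    gen_lt50_truth,
    gen_weather_series,
    segment_seasons,
)
from grapecold.curation import filter_quality


@pytest.fixture(scope="session")
def registry() -> CultivarRegistry:
    return CultivarRegistry.default()


@pytest.fixture(scope="session")
def weather_station():
    """One 4-year synthetic mid-latitude station: (meta, series)."""
    return gen_weather_series(WeatherGenConfig(), seed=101)


@pytest.fixture(scope="session")
def quality_season(weather_station):
    """The first dormant season passing the 220-day screen."""
    meta, series = weather_station
    seasons = [s for s in segment_seasons(series, meta) if filter_quality(s)]
    assert seasons, "fixture station must yield at least one full season"
    return seasons[0]


@pytest.fixture(scope="session")
def feature_table(weather_station, quality_season, registry) -> pd.DataFrame:
    """126-column predictor table for one season of Riesling."""
    meta, _ = weather_station
    return assemble_features(quality_season, meta.latitude, "Riesling", registry)


@pytest.fixture(scope="session")
def training_dataset(registry):
    """Feature rows with noisy (sigma = 1 C) synthetic LT50 labels, n >= 2000.

    Two stations x all full seasons x two cultivars; returns
    (features, observed, truth) with aligned row order.
    """
    lt50_cfg = Lt50GenConfig(noise_sigma_c=1.0)
    frames, observed_parts, truth_parts = [], [], []
    for st_idx, seed in enumerate([7, 8]):
        meta, series = gen_weather_series(
            WeatherGenConfig(latitude=43.0 + st_idx), seed=seed,
            station_id=f"SYNTRAIN{st_idx:02d}"
        )
        for season in segment_seasons(series, meta):
            if not filter_quality(season):
                continue
            for cv_idx, cultivar in enumerate(["Riesling", "Concord"]):
                feats = assemble_features(season, meta.latitude, cultivar, registry)
                truth, obs = gen_lt50_truth(
                    feats, lt50_cfg,
                    seed=1000 + 10 * st_idx + 2 * season.label % 97 + cv_idx,
                )
                frames.append(feats)
                observed_parts.append(obs)
                truth_parts.append(truth)
    features = pd.concat(frames, ignore_index=True)
    observed = pd.concat(observed_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    assert len(features) >= 2000
    return features, observed, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
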