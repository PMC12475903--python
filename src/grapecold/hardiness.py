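"""LT50 regression, evaluation, permutation importance and cold-damage scoring.

LT50 is the temperature that kills half of a grapevine's primary buds; it is
the scalar measure of bud cold hardiness and is always at or below 0 C
during the dormant season.  The regressor here is a gradient-boosted tree
ensemble trained on the 126-column predictor table; it is deliberately
pluggable (anything with fit/predict works) so a different regressor can be
swapped in without touching the rest of the pipeline.

Cold-damage potential converts a day's minimum temperature and predicted
LT50 into a 0-100 score with a logistic curve anchored at 10% when tmin is
2 C above LT50 and 90% when it is 2 C below; the unique logistic through
both anchors has steepness k = ln(9)/2 per degree C.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.model_selection import train_test_split

#: Logistic steepness fixed by the 10%/90% anchors at +/-2 C around LT50.
DAMAGE_K = math.log(9.0) / 2.0

#: Physiologically plausible LT50 interval, degrees C.
LT50_CLAMP = (-40.0, 0.0)

DEFAULT_HYPERPARAMETERS = {
    "max_iter": 300,
    "learning_rate": 0.1,
    "max_leaf_nodes": 31,
    "min_samples_leaf": 20,
}


@dataclass
class ModelBundle:
    """A fitted LT50 regressor plus everything needed to reuse it safely."""

    model: object
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Raw (unclamped) model output in feature-name order."""
        aligned = _align_features(features, self.feature_names)
        return np.asarray(self.model.predict(aligned.to_numpy()), dtype=float)


def _align_features(features: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    missing = [n for n in names if n not in features.columns]
    extra = [c for c in features.columns if c not in names]
    if missing or extra:
        raise ValueError(
            f"feature mismatch: missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    return features.loc[:, list(names)]


def train_surrogate(features: pd.DataFrame, lt50: Sequence[float],
                    seed: int = 0, holdout_fraction: float = 0.1,
                    hyperparameters: dict | None = None) -> ModelBundle:
    """Fit the gradient-boosted LT50 surrogate.

    A seeded ``holdout_fraction`` of rows (default 10%) is reserved before
    fitting and the bundle records the held-out RMSE in degrees C alongside
    the seed and hyperparameters.  Deterministic given the seed.
    """
    y = np.asarray(lt50, dtype=float)
    if len(features) != len(y):
        raise ValueError(f"{len(features)} feature rows vs {len(y)} labels")
    if len(y) < 50:
        raise ValueError(f"need at least 50 rows to train, got {len(y)}")
    if not np.isfinite(y).all():
        raise ValueError("labels contain non-finite values")
    if features.isna().any().any():
        raise ValueError("features contain missing values")

    params = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        params.update(hyperparameters)

    x_train, x_test, y_train, y_test = train_test_split(
        features, y, test_size=holdout_fraction, random_state=seed
    )
    model = HistGradientBoostingRegressor(random_state=seed, **params)
    model.fit(x_train.to_numpy(), y_train)

    bundle = ModelBundle(
        model=model,
        feature_names=list(features.columns),
        metadata={
            "seed": seed,
            "hyperparameters": params,
            "holdout_fraction": holdout_fraction,
            "n_train": len(x_train),
            "n_holdout": len(x_test),
        },
    )
    preds = predict_lt50(bundle, x_test)
    bundle.metadata["holdout_rmse_c"] = float(rmse(preds, y_test))
    return bundle


def predict_lt50(bundle: ModelBundle, features: pd.DataFrame,
                 clamp: tuple[float, float] = LT50_CLAMP) -> pd.Series:
    """Predict LT50 (degrees C) per row, clamped to the plausible interval."""
    raw = bundle.predict(features)
    lo, hi = clamp
    return pd.Series(np.clip(raw, lo, hi), index=features.index, name="lt50_c")


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean square error between paired predictions and observations."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def damage_potential(tmin, lt50):
    """Cold-damage potential (0-100) from daily minimum temperature and LT50.

    D = 100 / (1 + exp(k * (tmin - lt50))) with k = ln(9)/2, so that
    D = 10 when tmin = lt50 + 2, D = 90 when tmin = lt50 - 2 and D = 50 at
    tmin = lt50.  Works elementwise on scalars or arrays.
    """
    delta = np.asarray(tmin, dtype=float) - np.asarray(lt50, dtype=float)
    # clip the exponent far beyond float saturation to avoid overflow warnings
    out = 100.0 / (1.0 + np.exp(np.clip(DAMAGE_K * delta, -600.0, 600.0)))
    if np.ndim(out) == 0:
        return float(out)
    return out


def feature_importance(bundle: ModelBundle, features: pd.DataFrame,
                       labels: Sequence[float], n_permutations: int = 10,
                       seed: int = 0) -> pd.DataFrame:
    """Permutation importance on held-out rows.

    Importance of a feature = mean increase of the held-out RMSE over
    ``n_permutations`` independent shuffles of that column; ranked
    descending.  Rows must not have been used in training.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(labels, dtype=float)
    aligned = _align_features(features, bundle.feature_names)
    rng = np.random.default_rng(seed)
    baseline = rmse(predict_lt50(bundle, aligned), y)
    rows = []
    for name in bundle.feature_names:
        deltas = np.empty(n_permutations)
        for p in range(n_permutations):
            shuffled = aligned.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            deltas[p] = rmse(predict_lt50(bundle, shuffled), y) - baseline
        rows.append({
            "feature": name,
            "importance": float(deltas.mean()),
            "stderr": float(deltas.std(ddof=1) / math.sqrt(n_permutations))
            if n_permutations > 1 else float("nan"),
        })
    frame = pd.DataFrame(rows).sort_values(
        "importance", ascending=False, kind="stable"
    )
    return frame.reset_index(drop=True)


def save_bundle(bundle: ModelBundle, directory: str | Path) -> None:
    """Persist a bundle: joblib archive plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle.model, directory / "model.joblib")
    sidecar = {"feature_names": bundle.feature_names, "metadata": bundle.metadata}
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_bundle(directory: str | Path) -> ModelBundle:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    model = joblib.load(directory / "model.joblib")
    return ModelBundle(model=model,
                       feature_names=sidecar["feature_names"],
                       metadata=sidecar["metadata"])
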