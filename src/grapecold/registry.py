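"""Cultivar registry: the 54 grapevine cultivars the predictor one-hot encodes.

The model covers 21 *Vitis vinifera* and 33 interspecific hybrid cultivars;
the one-hot block contributes 54 of the 126 predictor columns, so a registry
must always contain exactly 54 uniquely named entries.  The default list
shipped here is a synthetic stand-in with the correct class composition,
built from real cultivar names grown in cool-climate viticulture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

REGISTRY_SIZE = 54
SPECIES_CLASSES = ("vinifera", "hybrid")

_DEFAULT_VINIFERA = [
    "Barbera", "Cabernet Franc", "Cabernet Sauvignon", "Chardonnay",
    "Gewurztraminer", "Gruner Veltliner", "Lemberger", "Malbec", "Merlot",
    "Nebbiolo", "Petit Verdot", "Pinot Gris", "Pinot Noir", "Riesling",
    "Sangiovese", "Sauvignon Blanc", "Semillon", "Syrah", "Tempranillo",
    "Viognier", "Zinfandel",
]

_DEFAULT_HYBRID = [
    "Aravelle", "Baco Noir", "Brianna", "Catawba", "Cayuga White",
    "Chambourcin", "Chancellor", "Chardonel", "Concord", "Corot Noir",
    "Crimson Pearl", "Delaware", "Edelweiss", "Elvira", "Frontenac",
    "Frontenac Gris", "Itasca", "La Crescent", "La Crosse", "Leon Millot",
    "Marechal Foch", "Marquette", "Niagara", "Noiret", "Norton",
    "Petite Pearl", "Seyval Blanc", "St Croix", "Traminette",
    "Valvin Muscat", "Verona", "Vidal Blanc", "Vignoles",
]


def _column_name(cultivar: str) -> str:
    return "cv_" + re.sub(r"[^A-Za-z0-9]+", "_", cultivar).strip("_").lower()


@dataclass(frozen=True)
class CultivarRegistry:
    """Ordered set of 54 cultivar names with a species class per entry."""

    names: tuple[str, ...]
    species: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != REGISTRY_SIZE:
            raise ValueError(
                f"registry must have exactly {REGISTRY_SIZE} cultivars, "
                f"got {len(self.names)}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("cultivar names must be unique")
        for name in self.names:
            cls = self.species.get(name)
            if cls not in SPECIES_CLASSES:
                raise ValueError(
                    f"cultivar {name!r}: species class must be one of "
                    f"{SPECIES_CLASSES}, got {cls!r}"
                )

    @classmethod
    def default(cls) -> "CultivarRegistry":
        names = tuple(sorted(_DEFAULT_VINIFERA + _DEFAULT_HYBRID))
        species = {n: "vinifera" for n in _DEFAULT_VINIFERA}
        species.update({n: "hybrid" for n in _DEFAULT_HYBRID})
        return cls(names=names, species=species)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CultivarRegistry":
        """Load a delimited registry with columns ``cultivar`` and ``species``."""
        frame = pd.read_csv(path)
        required = {"cultivar", "species"}
        if not required.issubset(frame.columns):
            raise ValueError(f"registry file needs columns {sorted(required)}")
        names = tuple(frame["cultivar"].astype(str))
        species = dict(zip(names, frame["species"].astype(str)))
        return cls(names=names, species=species)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"cultivar": self.names,
             "species": [self.species[n] for n in self.names]}
        ).to_csv(path, index=False)

    @property
    def column_names(self) -> list[str]:
        """Stable one-hot column names, in registry order."""
        return [_column_name(n) for n in self.names]

    def one_hot(self, cultivar: str) -> pd.Series:
        """0/1 indicator vector for one cultivar (errors on unknown names)."""
        if cultivar not in self.names:
            raise KeyError(
                f"unknown cultivar {cultivar!r}; registry has: "
                + ", ".join(self.names)
            )
        return pd.Series(
            [1.0 if n == cultivar else 0.0 for n in self.names],
            index=self.column_names,
        )

    def of_species(self, species: str) -> list[str]:
        return [n for n in self.names if self.species[n] == species]
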