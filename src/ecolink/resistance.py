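"""Integrated movement-resistance surface from a weighted six-factor overlay.

Each factor — land cover, relief, slope, distance to class-I roads, distance
to class-II roads, distance to pollution sources — is classified to a
per-class resistance value, and the integrated surface is the weighted sum
Σ w_f · class_value_f with weights (0.30, 0.15, 0.15, 0.15, 0.15, 0.10).
With the default table the most permeable combination scores exactly 1
(forest cover, high relief class, steep slope class, far from both road
classes and from pollution sources) and the least permeable scores 370.

Distance and terrain axes use interval classification; values above the
printed top interval clamp to the last class.  The pollution-distance rows
are read gap-free as breaks (0, 2000, 4000, 8000, 10000, ∞) → values
(100, 80, 60, 40, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid
from .landcover import NAME_TO_CODE

__all__ = ["FactorSpec", "ResistanceTable", "classify_factor", "integrated_resistance",
           "default_resistance_table", "RESISTANCE_FACTORS"]

RESISTANCE_FACTORS = ("lulc", "relief", "slope", "road1_dist", "road2_dist", "pollution_dist")


@dataclass
class FactorSpec:
    """One resistance factor: weight plus either a categorical or interval map.

    ``categories`` maps LULC codes to resistance values; ``breaks`` is an
    ascending edge list of length ``len(values) + 1`` (last edge may be
    inf) assigning ``values[i]`` to the half-open interval
    ``[breaks[i], breaks[i+1])``; values above the last finite edge clamp
    to the last class.
    """

    name: str
    weight: float
    categories: dict[int, float] | None = None
    breaks: list[float] | None = None
    values: list[float] | None = None

    def __post_init__(self) -> None:
        if (self.categories is None) == (self.breaks is None):
            raise ValueError(f"factor {self.name}: give exactly one of categories/breaks")
        if self.breaks is not None:
            if self.values is None or len(self.breaks) != len(self.values) + 1:
                raise ValueError(f"factor {self.name}: need len(breaks) == len(values)+1")
            if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
                raise ValueError(f"factor {self.name}: breaks must be ascending")
            if any(v <= 0 for v in self.values):
                raise ValueError(f"factor {self.name}: resistance values must be > 0")
        if self.categories is not None and any(v <= 0 for v in self.categories.values()):
            raise ValueError(f"factor {self.name}: resistance values must be > 0")

    def min_value(self) -> float:
        vals = self.values if self.values is not None else list(self.categories.values())
        return float(min(vals))

    def max_value(self) -> float:
        vals = self.values if self.values is not None else list(self.categories.values())
        return float(max(vals))


@dataclass
class ResistanceTable:
    """The six factor specs; weights must sum to 1."""

    factors: dict[str, FactorSpec]

    def __post_init__(self) -> None:
        total = sum(f.weight for f in self.factors.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"factor weights sum to {total}, expected 1")

    def min_resistance(self) -> float:
        """Weighted sum with every factor in its most permeable class."""
        return float(sum(f.weight * f.min_value() for f in self.factors.values()))

    def max_resistance(self) -> float:
        return float(sum(f.weight * f.max_value() for f in self.factors.values()))


def classify_factor(values: RasterGrid, spec: FactorSpec) -> RasterGrid:
    """Per-cell class resistance value for one factor raster."""
    v = values.values
    out = np.zeros(values.shape, dtype=float)
    if spec.categories is not None:
        codes = np.unique(v[values.valid_mask].astype(int))
        missing = [int(c) for c in codes if int(c) not in spec.categories]
        if missing:
            raise KeyError(f"factor {spec.name}: no resistance value for codes {missing}")
        for code, rv in spec.categories.items():
            out[v.astype(int) == code] = rv
    else:
        vals = np.nan_to_num(v.astype(float), nan=spec.breaks[-2])
        if np.any(vals[values.valid_mask] < spec.breaks[0]):
            raise ValueError(f"factor {spec.name}: value below first break")
        idx = np.searchsorted(spec.breaks[1:-1], vals, side="right")
        out = np.asarray(spec.values, dtype=float)[idx]
    out = out.astype(float)
    out[values.nodata_mask] = np.nan
    return values.with_values(out)


def integrated_resistance(
    factor_rasters: dict[str, RasterGrid], table: ResistanceTable
) -> RasterGrid:
    """Weighted overlay Σ w_f · classified_f over the six factor rasters."""
    missing = set(table.factors) - set(factor_rasters)
    if missing:
        raise ValueError(f"missing factor rasters: {sorted(missing)}")
    ref = next(iter(factor_rasters.values()))
    out = np.zeros(ref.shape, dtype=float)
    mask = np.zeros(ref.shape, dtype=bool)
    for name, spec in table.factors.items():
        r = factor_rasters[name]
        ref.require_congruent(r, name)
        classified = classify_factor(r, spec)
        out += spec.weight * np.nan_to_num(classified.values, nan=0.0)
        mask |= classified.nodata_mask
    out[mask] = np.nan
    return ref.with_values(out, mask)


INF = float("inf")


def default_resistance_table() -> ResistanceTable:
    """The default six-factor table (weights 0.3/0.15×4/0.1)."""
    c = NAME_TO_CODE
    lulc_values = {
        c["paddy_field"]: 100, c["irrigated_land"]: 90,
        c["forestland"]: 1, c["shrubland"]: 1, c["open_woodland"]: 1,
        c["other_forestland"]: 1,
        c["high_density_grassland"]: 50, c["middle_density_grassland"]: 60,
        c["low_density_grassland"]: 70,
        c["river"]: 10, c["lake"]: 10, c["pond"]: 10, c["beach_land"]: 10,
        c["urban_construction_land"]: 800, c["rural_construction_land"]: 700,
        c["mine"]: 1000,
        c["swampland"]: 50, c["bare"]: 50, c["rock"]: 50,
    }
    return ResistanceTable(factors={
        "lulc": FactorSpec("lulc", 0.30, categories={k: float(v) for k, v in lulc_values.items()}),
        "relief": FactorSpec("relief", 0.15,
                             breaks=[0, 25, 50, 75, 100, INF],
                             values=[100, 80, 60, 40, 1]),
        "slope": FactorSpec("slope", 0.15,
                            breaks=[0, 8, 15, 25, 35, INF],
                            values=[100, 80, 60, 40, 1]),
        "road1_dist": FactorSpec("road1_dist", 0.15,
                                 breaks=[0, 200, 400, 800, 1600, 3200, INF],
                                 values=[100, 80, 60, 40, 20, 1]),
        "road2_dist": FactorSpec("road2_dist", 0.15,
                                 breaks=[0, 150, 250, 450, 800, 1000, INF],
                                 values=[100, 80, 60, 40, 20, 1]),
        "pollution_dist": FactorSpec("pollution_dist", 0.10,
                                     breaks=[0, 2000, 4000, 8000, 10000, INF],
                                     values=[100, 80, 60, 40, 1]),
    })
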