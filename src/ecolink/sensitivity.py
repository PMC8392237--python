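"""Ecological-sensitivity layers: habitat and water sensitivity scores, CSLE soil loss.

Sensitivity scoring uses ordinal step functions on the scale {7, 5, 3, 1}
(7 = most sensitive).  Habitat sensitivity overlays four sub-scores —
distance to major roads, distance to natural reserves, land-cover class and
NDVI; water sensitivity overlays three — distance to surface water, to
wastewater sources/sewage plants, and to air-pollution sources.  Sub-scores
combine by unweighted arithmetic mean, which keeps the result on the 1–7
scale (a "sum" mode is available).

Soil erosion uses the Chinese Soil Loss Equation, the multiplicative factor
overlay A = R·K·LS·C·P·T (t·ha⁻¹·yr⁻¹): rainfall erosivity R, soil
erodibility K, topographic factor LS, vegetation-cover factor C, engineering
practice P and tillage practice T.

The three layers are integrated by min-max normalization, an equal-weight
mean, and a quartile classification into non / slightly / moderately /
extremely sensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid, minmax_normalize, quantile_classify
from . import landcover

__all__ = [
    "ScoreBreaks",
    "CSLEFactors",
    "score_layer",
    "lulc_habitat_score",
    "habitat_sensitivity",
    "water_sensitivity",
    "csle",
    "ls_factor",
    "integrated_sensitivity",
    "HABITAT_BREAKS",
    "WATER_BREAKS",
]

SENSITIVITY_SCORES = (7, 5, 3, 1)
SENSITIVITY_LEVELS = {
    1: "non-sensitive", 2: "slightly sensitive",
    3: "moderately sensitive", 4: "extremely sensitive",
}


@dataclass
class ScoreBreaks:
    """An ordinal step function: half-open intervals [lo, hi) → score.

    Intervals must partition the axis without gap or overlap; scores are
    drawn from {7, 5, 3, 1}.
    """

    intervals: list[tuple[float, float, int]]  # (lo, hi, score)
    units: str = "m"

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for (lo, hi, s) in ivs:
            if hi <= lo:
                raise ValueError(f"empty interval [{lo}, {hi})")
            if s not in SENSITIVITY_SCORES:
                raise ValueError(f"score {s} not in {SENSITIVITY_SCORES}")
        for (_lo, hi, _s), (lo2, _hi2, _s2) in zip(ivs, ivs[1:]):
            if not math.isclose(hi, lo2):
                raise ValueError("intervals do not partition the axis")
        self.intervals = ivs

    def lookup(self, values: np.ndarray) -> np.ndarray:
        edges = [iv[0] for iv in self.intervals][1:]
        scores = np.array([iv[2] for iv in self.intervals])
        lo0 = self.intervals[0][0]
        hi_last = self.intervals[-1][1]
        v = np.asarray(values, dtype=float)
        bad = (v < lo0) | (v >= hi_last)
        if np.any(bad & np.isfinite(v)):
            raise ValueError("value outside all score intervals")
        idx = np.searchsorted(edges, v, side="right")
        return scores[np.clip(idx, 0, len(scores) - 1)]


INF = float("inf")

# Sensitivity score standards: distance axes in metres, NDVI in [0, 1].
HABITAT_BREAKS = {
    "road_dist": ScoreBreaks([(0, 1000, 7), (1000, 2000, 5), (2000, 3000, 3), (3000, INF, 1)]),
    "reserve_dist": ScoreBreaks([(0, 3000, 7), (3000, 6000, 5), (6000, 9000, 3), (9000, INF, 1)]),
    "ndvi": ScoreBreaks([(0, 0.3, 1), (0.3, 0.5, 3), (0.5, 0.7, 5), (0.7, 1.0 + 1e-9, 7)], units="index"),
}
WATER_BREAKS = {
    "water_dist": ScoreBreaks([(0, 500, 7), (500, 1000, 5), (1000, 1500, 3), (1500, INF, 1)]),
    "wastewater_dist": ScoreBreaks([(0, 3000, 7), (3000, 6000, 5), (6000, 9000, 3), (9000, INF, 1)]),
    "air_pollution_dist": ScoreBreaks([(0, 4000, 7), (4000, 8000, 5), (8000, 12000, 3), (12000, INF, 1)]),
}

# land-cover class → habitat-sensibility score
_LULC_SCORE_BY_CAT = {
    "forest": 7, "water": 7, "wetland": 7,
    "grassland": 5, "cropland": 5,
    "barren": 3, "built": 1,
}


def score_layer(values: RasterGrid, breaks: ScoreBreaks) -> RasterGrid:
    """Per-cell interval lookup of a sensitivity score."""
    v = np.nan_to_num(values.values.astype(float), nan=breaks.intervals[0][0])
    out = breaks.lookup(v).astype(float)
    out[values.nodata_mask] = np.nan
    return values.with_values(out)


def lulc_habitat_score(lulc: RasterGrid) -> RasterGrid:
    """Habitat-sensibility score of the land-cover class itself."""
    lv = lulc.values.astype(int)
    out = np.zeros(lulc.shape, dtype=float)
    for code in np.unique(lv[lulc.valid_mask]):
        out[lv == code] = _LULC_SCORE_BY_CAT[landcover.category_of(int(code))]
    out[lulc.nodata_mask] = np.nan
    return lulc.with_values(out)


def _combine(scores: list[RasterGrid], mode: str) -> RasterGrid:
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    ref = scores[0]
    mask = np.zeros(ref.shape, dtype=bool)
    for s in scores:
        ref.require_congruent(s, "score layer")
        mask |= s.nodata_mask
    stack = np.stack([np.nan_to_num(s.values, nan=0.0) for s in scores])
    out = stack.mean(axis=0) if mode == "mean" else stack.sum(axis=0)
    out[mask] = np.nan
    return ref.with_values(out, mask)


def habitat_sensitivity(
    road_dist: RasterGrid,
    reserve_dist: RasterGrid,
    lulc: RasterGrid,
    ndvi: RasterGrid,
    breaks: dict[str, ScoreBreaks] | None = None,
    mode: str = "mean",
) -> RasterGrid:
    """Overlay of the four habitat sub-scores (road, reserve, cover, NDVI)."""
    b = breaks or HABITAT_BREAKS
    subs = [
        score_layer(road_dist, b["road_dist"]),
        score_layer(reserve_dist, b["reserve_dist"]),
        lulc_habitat_score(lulc),
        score_layer(ndvi, b["ndvi"]),
    ]
    return _combine(subs, mode)


def water_sensitivity(
    water_dist: RasterGrid,
    wastewater_dist: RasterGrid,
    air_pollution_dist: RasterGrid,
    breaks: dict[str, ScoreBreaks] | None = None,
    mode: str = "mean",
) -> RasterGrid:
    """Overlay of the three water sub-scores (surface water, wastewater, air)."""
    b = breaks or WATER_BREAKS
    subs = [
        score_layer(water_dist, b["water_dist"]),
        score_layer(wastewater_dist, b["wastewater_dist"]),
        score_layer(air_pollution_dist, b["air_pollution_dist"]),
    ]
    return _combine(subs, mode)


@dataclass
class CSLEFactors:
    """The six CSLE factor rasters (all congruent, all non-negative)."""

    R: RasterGrid   # rainfall erosivity, MJ·mm·ha⁻¹·h⁻¹·yr⁻¹
    K: RasterGrid   # soil erodibility, t·h·MJ⁻¹·mm⁻¹
    LS: RasterGrid  # slope length-steepness, dimensionless
    C: RasterGrid   # vegetation cover, dimensionless
    P: RasterGrid   # engineering practice, dimensionless
    T: RasterGrid   # tillage practice, dimensionless

    def as_list(self) -> list[RasterGrid]:
        return [self.R, self.K, self.LS, self.C, self.P, self.T]


def csle(factors: CSLEFactors) -> RasterGrid:
    """Soil loss A = R·K·LS·C·P·T (t·ha⁻¹·yr⁻¹): cellwise factor product."""
    rasters = factors.as_list()
    ref = rasters[0]
    mask = np.zeros(ref.shape, dtype=bool)
    out = np.ones(ref.shape, dtype=float)
    for r in rasters:
        ref.require_congruent(r, "CSLE factor")
        if np.any(r.valid_values < 0):
            raise ValueError("CSLE factors must be >= 0")
        out *= np.nan_to_num(r.values, nan=1.0)
        mask |= r.nodata_mask
    out[mask] = np.nan
    return ref.with_values(out, mask)


def ls_factor(dem: RasterGrid, slope_deg: RasterGrid | None = None) -> RasterGrid:
    """Simple LS estimate from terrain: optional helper, not a calibrated model.

    Uses the common slope-length/steepness approximation
    ``LS = (l/22.13)^0.4 · (sin θ / 0.0896)^1.3`` with the flow-path length
    ``l`` fixed at one cell — adequate for a synthetic factor surface.
    """
    from .grid import slope as slope_op

    s = slope_deg if slope_deg is not None else slope_op(dem)
    theta = np.radians(np.nan_to_num(s.values, nan=0.0))
    ls = (dem.cell_size / 22.13) ** 0.4 * (np.sin(theta) / 0.0896) ** 1.3
    ls[dem.nodata_mask] = np.nan
    return dem.with_values(ls)


def integrated_sensitivity(
    habitat_s: RasterGrid,
    water_s: RasterGrid,
    soil_loss: RasterGrid,
) -> tuple[RasterGrid, RasterGrid]:
    """Equal-weight mean of the min-max-normalized layers, plus 4 quantile levels.

    Returns ``(index in [0, 1], classes 1..4)`` where class 4 is
    "extremely sensitive".
    """
    habitat_s.require_congruent(water_s, "water sensitivity")
    habitat_s.require_congruent(soil_loss, "soil loss")
    layers = [minmax_normalize(r) for r in (habitat_s, water_s, soil_loss)]
    mask = np.zeros(habitat_s.shape, dtype=bool)
    for r in layers:
        mask |= r.nodata_mask
    stack = np.stack([np.nan_to_num(r.values, nan=0.0) for r in layers])
    index = stack.mean(axis=0)
    index[mask] = np.nan
    index_grid = habitat_s.with_values(index, mask)
    classes = quantile_classify(index_grid, 4)
    return index_grid, classes
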