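"""Ecosystem-service raster models: habitat quality, water yield, carbon storage.

Habitat quality follows the InVEST formulation.  Each anthropogenic threat
``r`` has a weight ``W_r``, a maximum effective distance ``d_rmax`` and a
distance-decay kind; its impact on a cell at distance ``d`` is

    linear:       i = 1 − d/d_rmax
    exponential:  i = exp(−(2.99/d_rmax)·d)

with a hard cutoff ``i = 0`` beyond ``d_rmax``.  Degradation ``D`` of a cell
with land cover ``j`` is the threat-weight-normalized average of
``impact × S_jr`` over threats, where ``S_jr`` is the sensitivity of cover
``j`` to threat ``r`` and the accessibility factor β is fixed at 1.  Quality
is then a half-saturation decay of suitability:

    Q = H_j · (1 − D^z / (D^z + k^z))

so quality halves at degradation ``D = k`` (default k = 0.5, z = 2.5).

Annual water yield is the pixel water balance ``Y = (1 − AET/P)·P = P − AET``,
and carbon storage is the per-cover sum of four pools (above-ground,
below-ground, soil, dead organic matter) in t·ha⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid, euclidean_distance, minmax_normalize
from . import landcover

log = logging.getLogger(__name__)

__all__ = [
    "ThreatSpec",
    "HabitatParams",
    "CarbonPoolTable",
    "threat_impact",
    "degradation",
    "habitat_quality",
    "water_yield",
    "carbon_storage",
    "integrated_services",
    "default_threats",
    "default_habitat_params",
    "default_carbon_pools",
]

EXP_DECAY_CONSTANT = 2.99  # impact falls to e^-2.99 ≈ 0.05 at d_rmax


@dataclass
class ThreatSpec:
    """One threat layer: weight, max effective distance, decay kind, source raster.

    ``source`` is a raster in [0, 1] marking where the threat originates
    (typically binary presence).  Threat weights are renormalized to sum to
    1 across all threats before use.
    """

    id: str
    weight: float
    d_max_m: float
    decay: str  # "linear" | "exponential"
    source: RasterGrid | None = None

    def __post_init__(self) -> None:
        if self.d_max_m <= 0:
            raise ValueError(f"threat {self.id}: d_max_m must be > 0")
        if not 0 <= self.weight <= 1:
            raise ValueError(f"threat {self.id}: weight must be in [0, 1]")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"threat {self.id}: unknown decay {self.decay!r}")


@dataclass
class HabitatParams:
    """Per-LULC habitat suitability and per-threat sensitivity.

    ``suitability[j]`` is H_j in [0, 1]; ``sensitivity[j][r]`` is S_jr in
    [0, 1].  ``half_saturation`` is k; ``exponent`` is z (2.5).  The
    accessibility factor β is fixed at 1.
    """

    suitability: dict[int, float]
    sensitivity: dict[int, dict[str, float]]
    half_saturation: float = 0.5
    exponent: float = 2.5

    def __post_init__(self) -> None:
        if self.half_saturation <= 0 or self.exponent <= 0:
            raise ValueError("half_saturation and exponent must be > 0")
        for j, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ValueError(f"suitability H_{j} outside [0, 1]")
        for j, row in self.sensitivity.items():
            for r, s in row.items():
                if not 0 <= s <= 1:
                    raise ValueError(f"sensitivity S[{j}][{r}] outside [0, 1]")


@dataclass
class CarbonPoolTable:
    """Per-LULC carbon densities (t·ha⁻¹) in four pools."""

    pools: dict[int, tuple[float, float, float, float]]  # above, below, soil, dead

    def __post_init__(self) -> None:
        for code, p in self.pools.items():
            if any(v < 0 for v in p):
                raise ValueError(f"carbon pools for LULC {code} must be >= 0")

    def total(self, code: int) -> float:
        if code not in self.pools:
            raise KeyError(f"LULC code {code} absent from carbon pool table")
        return float(sum(self.pools[code]))


def threat_impact(d_m, spec: ThreatSpec):
    """Impact i of a threat at distance ``d_m`` (m); scalar or array.

    Zero beyond the maximum effective distance for both decay kinds.
    """
    d = np.asarray(d_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if spec.decay == "linear":
        i = 1.0 - d / spec.d_max_m
    else:
        i = np.exp(-(EXP_DECAY_CONSTANT / spec.d_max_m) * d)
    i = np.where(d > spec.d_max_m, 0.0, i)
    i = np.clip(i, 0.0, 1.0)
    return float(i) if np.isscalar(d_m) else i


def degradation(
    lulc: RasterGrid,
    threats: list[ThreatSpec],
    params: HabitatParams,
    mode: str = "nearest",
) -> RasterGrid:
    """Habitat degradation D per cell: normalized-weight average of threat levels.

    ``mode="nearest"`` (default) scores each threat by the impact of the
    nearest source cell — the scale-free reading of the weighted-average
    formulation.  ``mode="sum"`` instead sums impacts over every source
    cell and clips the per-threat level to 1.
    """
    if mode not in ("nearest", "sum"):
        raise ValueError("mode must be 'nearest' or 'sum'")
    codes = np.unique(lulc.valid_values.astype(int))
    for j in codes:
        for t in threats:
            if int(j) not in params.sensitivity or t.id not in params.sensitivity[int(j)]:
                raise KeyError(f"missing sensitivity entry for (lulc={int(j)}, threat={t.id!r})")
    w_total = sum(t.weight for t in threats)
    if w_total <= 0:
        raise ValueError("threat weights sum to zero")

    d_total = np.zeros(lulc.shape, dtype=float)
    lvals = lulc.values.astype(int)
    for t in threats:
        if t.source is None:
            raise ValueError(f"threat {t.id} has no source raster")
        lulc.require_congruent(t.source, f"threat {t.id} source")
        present = (t.source.values > 0) & t.source.valid_mask
        if not present.any():
            continue  # absent threat contributes zero degradation
        if mode == "nearest":
            dist = euclidean_distance(lulc, present).values
            impact = threat_impact(np.nan_to_num(dist, nan=np.inf), t)
            impact = impact * 1.0  # nearest source has r_y = 1 by presence
        else:
            rows, cols = np.nonzero(present)
            ry = t.source.values[rows, cols]
            rr, cc = np.indices(lulc.shape)
            impact = np.zeros(lulc.shape, dtype=float)
            for y, x, r_y in zip(rows, cols, ry):
                d = np.hypot(rr - y, cc - x) * lulc.cell_size
                impact += r_y * threat_impact(d, t)
            impact = np.clip(impact, 0.0, 1.0)
        s_jr = np.vectorize(lambda j: params.sensitivity[int(j)][t.id])(lvals)
        d_total += (t.weight / w_total) * impact * s_jr  # β_x = 1

    d_total[lulc.nodata_mask] = np.nan
    return lulc.with_values(d_total)


def habitat_quality(D: RasterGrid, lulc: RasterGrid, params: HabitatParams) -> RasterGrid:
    """Habitat quality Q = H_j · (1 − D^z/(D^z + k^z)), in [0, H_j]."""
    D.require_congruent(lulc, "lulc")
    k, z = params.half_saturation, params.exponent
    lvals = lulc.values.astype(int)
    missing = set(np.unique(lvals[lulc.valid_mask])) - set(params.suitability)
    if missing:
        raise KeyError(f"no suitability for LULC codes {sorted(missing)}")
    h = np.vectorize(lambda j: params.suitability.get(int(j), 0.0))(lvals).astype(float)
    d = np.clip(np.nan_to_num(D.values, nan=0.0), 0.0, None)
    q = h * (1.0 - d ** z / (d ** z + k ** z))
    q[D.nodata_mask | lulc.nodata_mask] = np.nan
    return D.with_values(q, D.nodata_mask | lulc.nodata_mask)


def water_yield(precipitation: RasterGrid, aet: RasterGrid) -> RasterGrid:
    """Annual water yield Y = (1 − AET/P)·P = P − AET (mm/yr); Y = 0 where P = 0."""
    precipitation.require_congruent(aet, "aet")
    p = precipitation.values.astype(float)
    a = aet.values.astype(float)
    ok = precipitation.valid_mask & aet.valid_mask
    if np.any(p[ok] < 0) or np.any(a[ok] < 0):
        raise ValueError("negative precipitation or AET")
    y = np.where(p > 0, p - a, 0.0)
    mask = ~ok
    y[mask] = np.nan
    return precipitation.with_values(y, mask)


def carbon_storage(lulc: RasterGrid, pools: CarbonPoolTable) -> RasterGrid:
    """Per-cell total carbon density (t·ha⁻¹): four-pool sum looked up by cover."""
    lvals = lulc.values.astype(int)
    totals = {code: pools.total(code) for code in np.unique(lvals[lulc.valid_mask])}
    out = np.zeros(lulc.shape, dtype=float)
    for code, tot in totals.items():
        out[lvals == code] = tot
    out[lulc.nodata_mask] = np.nan
    return lulc.with_values(out)


def integrated_services(Q: RasterGrid, Y: RasterGrid, C: RasterGrid) -> RasterGrid:
    """Equal-weight mean of the min-max-normalized service layers, in [0, 1]."""
    Q.require_congruent(Y, "water yield")
    Q.require_congruent(C, "carbon")
    layers = [minmax_normalize(r) for r in (Q, Y, C)]
    mask = np.zeros(Q.shape, dtype=bool)
    for r in layers:
        mask |= r.nodata_mask
    stack = np.stack([np.nan_to_num(r.values, nan=0.0) for r in layers])
    mean = stack.mean(axis=0)
    mean[mask] = np.nan
    return Q.with_values(mean, mask)


# -- default parameter tables ------------------------------------------------
#
# Typical InVEST-style values for a cropland-dominated plain; editable via
# the CSV interfaces in the pipeline config.

def default_threats(lulc: RasterGrid, roads_1=None, roads_2=None) -> list[ThreatSpec]:
    """Threat set: urban, rural and mining construction, arable land, roads.

    Source rasters are derived from the LULC grid (and road lines when
    given).  Weights/distances are conventional habitat-quality settings.
    """
    from .grid import rasterize_lines

    lv = lulc.values.astype(int)

    def presence(codes) -> RasterGrid:
        return lulc.with_values((np.isin(lv, list(codes))).astype(float))

    threats = [
        ThreatSpec("urban", 1.0, 8000.0, "exponential",
                   presence([landcover.NAME_TO_CODE["urban_construction_land"]])),
        ThreatSpec("rural", 0.7, 5000.0, "exponential",
                   presence([landcover.NAME_TO_CODE["rural_construction_land"]])),
        ThreatSpec("other_construction", 0.8, 6000.0, "exponential",
                   presence([landcover.NAME_TO_CODE["mine"]])),
        ThreatSpec("arable", 0.5, 3000.0, "linear",
                   presence(sorted(landcover.CROPLAND))),
    ]
    if roads_1 is not None:
        mask = rasterize_lines(lulc, roads_1).astype(float)
        threats.append(ThreatSpec("main_road", 0.8, 4000.0, "linear", lulc.with_values(mask)))
    if roads_2 is not None:
        mask = rasterize_lines(lulc, roads_2).astype(float)
        threats.append(ThreatSpec("railroad", 0.6, 3000.0, "linear", lulc.with_values(mask)))
    return threats


def default_habitat_params() -> HabitatParams:
    """Suitability/sensitivity defaults by coarse cover category."""
    suit_by_cat = {
        "forest": 1.0, "water": 0.9, "wetland": 1.0, "grassland": 0.8,
        "cropland": 0.4, "barren": 0.2, "built": 0.0,
    }
    sens_by_cat = {
        "forest": 0.8, "water": 0.7, "wetland": 0.9, "grassland": 0.6,
        "cropland": 0.4, "barren": 0.3, "built": 0.0,
    }
    threat_ids = ["urban", "rural", "other_construction", "arable", "main_road", "railroad"]
    suitability: dict[int, float] = {}
    sensitivity: dict[int, dict[str, float]] = {}
    for code in landcover.LULC_LEGEND:
        cat = landcover.category_of(code)
        suitability[code] = suit_by_cat[cat]
        base = sens_by_cat[cat]
        # habitat is less sensitive to arable encroachment than to built-up threats
        sensitivity[code] = {
            t: (base * 0.5 if t == "arable" else base) for t in threat_ids
        }
    return HabitatParams(suitability=suitability, sensitivity=sensitivity)


def default_carbon_pools() -> CarbonPoolTable:
    """Four-pool carbon densities (t·ha⁻¹) by cover class."""
    by_cat = {
        "forest": (45.0, 12.0, 90.0, 4.0),
        "wetland": (15.0, 8.0, 120.0, 3.0),
        "grassland": (6.0, 10.0, 70.0, 1.0),
        "cropland": (5.0, 2.0, 55.0, 0.5),
        "water": (0.5, 0.0, 20.0, 0.0),
        "barren": (0.5, 0.5, 15.0, 0.0),
        "built": (1.0, 0.5, 25.0, 0.0),
    }
    return CarbonPoolTable(
        pools={code: by_cat[landcover.category_of(code)] for code in landcover.LULC_LEGEND}
    )
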