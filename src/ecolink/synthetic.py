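"""Seeded synthetic landscapes for exercising the full pipeline at desk scale.

Real regional GIS stacks (30 m LULC, SRTM terrain, meteorological surfaces,
road and pollution-source layers, statutory reserve polygons) are large and
rarely redistributable.  This module generates landscapes with the *structure*
the analysis assumes — clustered land-cover classes, smooth terrain,
spatially autocorrelated climate fields, line roads, scattered pollution
points and reserve polygons — so every stage from service modelling to
circuit-theory corridor mapping runs reproducibly from a single seed.

Random fields are white noise smoothed with a Gaussian kernel of the
configured correlation length: the simplest generator with controllable
spatial autocorrelation.  Land cover is the field thresholded at the
cumulative class-proportion quantiles, which yields contiguous clustered
classes whose realized shares match the requested proportions up to ties.

Named fixtures with planted connectivity structure ("uniform", "hourglass",
"wall", "two_patch") are shipped as code for tests and worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box

from .grid import RasterGrid
from .landcover import NAME_TO_CODE

__all__ = ["LandscapeConfig", "LandscapeBundle", "generate", "make_fixture"]


# Default class proportions follow the land-cover composition of a
# cropland-dominated alluvial plain: ~62% cropland, ~16% forest, ~13% water,
# ~8% built-up, with traces of grassland and barren land.
DEFAULT_PROPORTIONS: dict[int, float] = {
    NAME_TO_CODE["paddy_field"]: 0.35,
    NAME_TO_CODE["irrigated_land"]: 0.27,
    NAME_TO_CODE["forestland"]: 0.16,
    NAME_TO_CODE["river"]: 0.05,
    NAME_TO_CODE["lake"]: 0.08,
    NAME_TO_CODE["urban_construction_land"]: 0.05,
    NAME_TO_CODE["rural_construction_land"]: 0.03,
    NAME_TO_CODE["high_density_grassland"]: 0.005,
    NAME_TO_CODE["bare"]: 0.005,
}


@dataclass
class LandscapeConfig:
    """Parameters of one synthetic landscape.

    ``class_proportions`` maps LULC codes to target area shares (must sum
    to 1); ``correlation_length`` is the Gaussian smoothing length in cells
    controlling how clustered all random fields are.  Climate fields are
    mm/yr; ``relief_m`` scales the DEM's total elevation range.
    """

    shape: tuple[int, int] = (120, 120)
    cell_size: float = 30.0
    class_proportions: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    correlation_length: float = 8.0
    n_roads_1: int = 2
    n_roads_2: int = 3
    n_pollution_points: int = 5
    n_reserves: int = 3
    reserve_radius_cells: float = 10.0
    precip_mean: float = 1150.0   # mm/yr, humid subtropical plain
    precip_spatial_sd: float = 120.0
    relief_m: float = 150.0
    base_elevation_m: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-6:
            raise ValueError("class_proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be >= 0")
        for name in ("n_roads_1", "n_roads_2", "n_pollution_points", "n_reserves"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")


@dataclass
class LandscapeBundle:
    """All input layers of one landscape, on a single congruent grid."""

    lulc: RasterGrid
    dem: RasterGrid
    precipitation: RasterGrid
    aet: RasterGrid
    ndvi: RasterGrid
    roads_1: list
    roads_2: list
    pollution_points: list
    reserves: list
    seed: int

    def rasters(self) -> dict[str, RasterGrid]:
        return {
            "lulc": self.lulc,
            "dem": self.dem,
            "precipitation": self.precipitation,
            "aet": self.aet,
            "ndvi": self.ndvi,
        }

    def validate(self) -> None:
        ref = self.lulc
        for name, r in self.rasters().items():
            ref.require_congruent(r, name)
        ok = self.aet.valid_mask & self.precipitation.valid_mask
        if np.any(self.aet.values[ok] > self.precipitation.values[ok] + 1e-9):
            raise ValueError("AET exceeds precipitation somewhere")
        nv = self.ndvi.valid_values
        if nv.size and (nv.min() < -1e-9 or nv.max() > 1 + 1e-9):
            raise ValueError("NDVI outside [0, 1]")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ``corr`` cells."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=max(corr, 1e-6), mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _unit(f: np.ndarray) -> np.ndarray:
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)


def _random_polyline(rng: np.random.Generator, width: float, height: float) -> LineString:
    """A jittered line crossing the full extent edge to edge."""
    if rng.random() < 0.5:  # west-east
        p0 = (0.0, rng.uniform(0, height))
        p1 = (width, rng.uniform(0, height))
    else:  # north-south
        p0 = (rng.uniform(0, width), 0.0)
        p1 = (rng.uniform(0, width), height)
    mid = (
        (p0[0] + p1[0]) / 2 + rng.uniform(-0.1, 0.1) * width,
        (p0[1] + p1[1]) / 2 + rng.uniform(-0.1, 0.1) * height,
    )
    return LineString([p0, mid, p1])


def generate(config: LandscapeConfig) -> LandscapeBundle:
    """Generate a fully seeded :class:`LandscapeBundle` from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    nrow, ncol = shape
    cs = config.cell_size
    width, height = ncol * cs, nrow * cs
    origin = (0.0, float(height))

    def grid(values: np.ndarray) -> RasterGrid:
        return RasterGrid(values, cs, origin)

    # land cover: threshold one clustered field at cumulative-share quantiles
    codes = list(config.class_proportions)
    props = np.array([config.class_proportions[c] for c in codes])
    f_lulc = _smooth_field(rng, shape, config.correlation_length)
    cum = np.cumsum(props)[:-1]
    breaks = np.quantile(f_lulc, cum) if cum.size else np.array([])
    idx = np.searchsorted(breaks, f_lulc, side="left")
    lulc = np.asarray(codes, dtype=int)[idx]

    dem = config.base_elevation_m + config.relief_m * _unit(
        _smooth_field(rng, shape, config.correlation_length * 1.5)
    )
    precip = config.precip_mean + config.precip_spatial_sd * _smooth_field(
        rng, shape, config.correlation_length
    )
    precip = np.clip(precip, 0.0, None)
    # AET as a smooth fraction of precipitation keeps 0 <= AET <= P and
    # water yield strictly positive and spatially structured
    aet_frac = 0.2 + 0.7 * _unit(_smooth_field(rng, shape, config.correlation_length))
    aet = precip * aet_frac
    ndvi = 0.05 + 0.9 * _unit(_smooth_field(rng, shape, config.correlation_length))

    roads_1 = [_random_polyline(rng, width, height) for _ in range(config.n_roads_1)]
    roads_2 = [_random_polyline(rng, width, height) for _ in range(config.n_roads_2)]
    pollution = [
        Point(rng.uniform(0, width), rng.uniform(0, height))
        for _ in range(config.n_pollution_points)
    ]
    reserves = []
    for _ in range(config.n_reserves):
        c = Point(rng.uniform(0.2 * width, 0.8 * width), rng.uniform(0.2 * height, 0.8 * height))
        reserves.append(c.buffer(config.reserve_radius_cells * cs))

    bundle = LandscapeBundle(
        lulc=grid(lulc), dem=grid(dem), precipitation=grid(precip),
        aet=grid(aet), ndvi=grid(ndvi),
        roads_1=roads_1, roads_2=roads_2,
        pollution_points=pollution, reserves=reserves, seed=config.seed,
    )
    bundle.validate()
    return bundle


# -- planted-structure fixtures ---------------------------------------------


def _constant_bundle(shape, cell_size, lulc_code, nodata=None) -> LandscapeBundle:
    nrow, ncol = shape
    origin = (0.0, nrow * cell_size)
    mask = np.zeros(shape, dtype=bool) if nodata is None else nodata

    def grid(v):
        vals = np.full(shape, float(v))
        return RasterGrid(vals, cell_size, origin, mask.copy())

    lulc = RasterGrid(np.full(shape, lulc_code, dtype=int), cell_size, origin, mask.copy())
    return LandscapeBundle(
        lulc=lulc, dem=grid(100.0), precipitation=grid(1100.0),
        aet=grid(600.0), ndvi=grid(0.6),
        roads_1=[], roads_2=[], pollution_points=[], reserves=[], seed=0,
    )


def _block_polygon(r: RasterGrid, r0: int, r1: int, c0: int, c1: int) -> Polygon:
    """Polygon covering cells rows [r0, r1) × cols [c0, c1)."""
    cs = r.cell_size
    x0, y0 = r.origin
    return box(x0 + c0 * cs, y0 - r1 * cs, x0 + c1 * cs, y0 - r0 * cs)


def make_fixture(name: str, shape: tuple[int, int] = (60, 60), cell_size: float = 30.0) -> LandscapeBundle:
    """Named small presets with planted connectivity structure.

    - ``"uniform"``: one LULC class, flat terrain, constant climate — every
      derived surface is constant.
    - ``"two_patch"``: uniform forest with two reserve blocks at opposite
      corners.
    - ``"hourglass"``: two habitat blocks joined by a single 1-cell-wide
      bridge; everything outside the blocks and bridge is nodata, so all
      flow between the blocks must cross the bridge.
    - ``"wall"``: uniform permeable forest crossed top-to-bottom by a
      built-up strip with no gap; reserves sit on either side, so every
      left-to-right path pays the wall's resistance.
    """
    forest = NAME_TO_CODE["forestland"]
    urban = NAME_TO_CODE["urban_construction_land"]
    nrow, ncol = shape

    if name == "uniform":
        return _constant_bundle(shape, cell_size, forest)

    if name == "two_patch":
        b = _constant_bundle(shape, cell_size, forest)
        k = max(nrow // 6, 2)
        b.reserves = [
            _block_polygon(b.lulc, 1, 1 + k, 1, 1 + k),
            _block_polygon(b.lulc, nrow - 1 - k, nrow - 1, ncol - 1 - k, ncol - 1),
        ]
        return b

    if name == "hourglass":
        r0, r1 = nrow // 4, 3 * nrow // 4
        ca0, ca1 = 1, ncol // 3
        cb0, cb1 = 2 * ncol // 3, ncol - 1
        bridge_row = nrow // 2
        valid = np.zeros(shape, dtype=bool)
        valid[r0:r1, ca0:ca1] = True
        valid[r0:r1, cb0:cb1] = True
        valid[bridge_row, ca1:cb0] = True
        b = _constant_bundle(shape, cell_size, forest, nodata=~valid)
        b.reserves = [
            _block_polygon(b.lulc, r0, r1, ca0, ca1),
            _block_polygon(b.lulc, r0, r1, cb0, cb1),
        ]
        return b

    if name == "wall":
        b = _constant_bundle(shape, cell_size, forest)
        w0 = ncol // 2 - 1
        lulc = b.lulc.values.copy()
        lulc[:, w0:w0 + 3] = urban
        b.lulc = b.lulc.with_values(lulc)
        k = max(nrow // 6, 2)
        mid0 = nrow // 2 - k // 2
        b.reserves = [
            _block_polygon(b.lulc, mid0, mid0 + k, 2, 2 + k),
            _block_polygon(b.lulc, mid0, mid0 + k, ncol - 2 - k, ncol - 2),
        ]
        return b

    raise ValueError(f"unknown fixture {name!r}")
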