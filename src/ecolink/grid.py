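"""Raster primitives shared by every stage of the pipeline.

All layers of one analysis live on a common grid: same shape, cell size and
top-left origin.  :class:`RasterGrid` is the common currency — a 2-D array of
cell values plus a boolean nodata mask that propagates through every cellwise
operation.  Distances are metres, areas km², coordinates refer to cell
centres in a row-major grid whose origin is the top-left corner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "RasterGrid",
    "PatchLabeling",
    "minmax_normalize",
    "quantile_classify",
    "euclidean_distance",
    "slope",
    "relief",
    "connected_patches",
    "zonal_mean",
    "rasterize_points",
    "rasterize_lines",
    "rasterize_polygons",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class RasterGrid:
    """A single-band raster: values, cell size (m), top-left origin, nodata mask.

    Parameters
    ----------
    values
        2-D array of cell values (float or integer codes).
    cell_size
        Edge length of a square cell in metres; must be positive.
    origin
        ``(x0, y0)`` map coordinates of the top-left corner of the grid.
    nodata_mask
        Boolean array, ``True`` where the cell holds no data.  Defaults to
        all-valid.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape differs from values shape")

    # -- basic introspection -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def congruent(self, other: "RasterGrid") -> bool:
        """Same shape, cell size and origin (layers of one analysis)."""
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_congruent(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.congruent(other):
            raise ValueError(f"{what} is not congruent with the reference grid")

    def with_values(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """A new grid on the same georeference with different cell values."""
        mask = self.nodata_mask if nodata_mask is None else nodata_mask
        return RasterGrid(np.asarray(values), self.cell_size, self.origin, mask.copy())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell centre; y decreases with row."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrow) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col


@dataclass
class PatchLabeling:
    """Connected patches of a boolean raster.

    ``labels`` holds integer patch ids (0 = background); ``areas`` maps each
    label to its area in km² (cell count × cell_size² / 10⁶).
    """

    labels: np.ndarray
    areas: dict[int, float]
    connectivity: int  # 4 or 8
    cell_size: float

    @property
    def n_patches(self) -> int:
        return len(self.areas)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


# -- cellwise operations ----------------------------------------------------


def minmax_normalize(r: RasterGrid) -> RasterGrid:
    """Rescale valid cells to [0, 1] by (v − min)/(max − min).

    A constant raster normalizes to all zeros (with a logged warning) so
    downstream equal-weight sums stay defined.
    """
    vals = r.valid_values.astype(float)
    if vals.size == 0:
        raise ValueError("raster has no valid cells")
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros(r.shape, dtype=float)
    if hi == lo:
        log.warning("minmax_normalize: constant raster (value %g) -> all zeros", lo)
    else:
        out[r.valid_mask] = (vals - lo) / (hi - lo)
    out[r.nodata_mask] = np.nan
    return r.with_values(out)


def quantile_classify(r: RasterGrid, n_classes: int) -> RasterGrid:
    """Rank-based classification into ``n_classes`` equal-count classes 1..n.

    Class ``c`` holds the cells whose rank fraction falls in ((c−1)/n, c/n];
    tied values all take the lower class, so the map is a monotone function
    of the cell value.  With fewer distinct values than classes some classes
    collapse (a warning is logged).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    vals = r.valid_values.astype(float)
    if vals.size == 0:
        raise ValueError("raster has no valid cells")
    order = np.sort(vals)
    n = vals.size
    # minimum rank of each value = 1 + number of strictly smaller values;
    # classing by the minimum rank sends tied values to the lower class
    min_rank = np.searchsorted(order, vals, side="left") + 1
    classes = np.floor((min_rank - 1) * n_classes / n).astype(int) + 1
    classes = np.clip(classes, 1, n_classes)
    if np.unique(vals).size < n_classes:
        log.warning(
            "quantile_classify: only %d distinct values for %d classes; classes collapse",
            np.unique(vals).size, n_classes,
        )
    out = np.zeros(r.shape, dtype=int)
    out[r.valid_mask] = classes
    return r.with_values(out)


def euclidean_distance(r: RasterGrid, targets: np.ndarray) -> RasterGrid:
    """Per-cell Euclidean distance in metres to the nearest target cell.

    ``targets`` is a boolean grid; target cells are at distance 0.  Raises if
    the target set is empty.
    """
    targets = np.asarray(targets, dtype=bool)
    if targets.shape != r.shape:
        raise ValueError("target mask shape differs from grid shape")
    if not targets.any():
        raise ValueError("euclidean_distance: empty target set")
    dist = ndimage.distance_transform_edt(~targets, sampling=r.cell_size)
    dist = dist.astype(float)
    dist[r.nodata_mask] = np.nan
    return r.with_values(dist)


def slope(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees from a 3×3 finite-difference gradient of the DEM."""
    z = dem.values.astype(float)
    if min(z.shape) == 1:
        grad = np.zeros_like(z)
    else:
        gy, gx = np.gradient(z, dem.cell_size)
        grad = np.hypot(gx, gy)
    deg = np.degrees(np.arctan(grad))
    deg[dem.nodata_mask] = np.nan
    return dem.with_values(deg)


def relief(dem: RasterGrid, window: int = 3) -> RasterGrid:
    """Focal relief: max − min elevation over a square window (cells)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("relief window must be a positive odd number of cells")
    z = dem.values.astype(float)
    if min(z.shape) == 1 or window == 1:
        out = np.zeros_like(z)
    else:
        # nodata cells must not contribute to the focal extremes
        hi_in = np.where(dem.nodata_mask, -np.inf, z)
        lo_in = np.where(dem.nodata_mask, np.inf, z)
        hi = ndimage.maximum_filter(hi_in, size=window, mode="nearest")
        lo = ndimage.minimum_filter(lo_in, size=window, mode="nearest")
        out = hi - lo
        out[~np.isfinite(out)] = 0.0
    out[dem.nodata_mask] = np.nan
    return dem.with_values(out)


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def connected_patches(r: RasterGrid, mask: np.ndarray, connectivity: int = 8) -> PatchLabeling:
    """Label connected patches of a boolean mask; areas in km²."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool) & r.valid_mask
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    cell_km2 = r.cell_size ** 2 / 1e6
    areas = {lab: counts[lab] * cell_km2 for lab in range(1, n + 1)}
    return PatchLabeling(labels=labels, areas=areas, connectivity=connectivity, cell_size=r.cell_size)


def zonal_mean(values: RasterGrid, zones: PatchLabeling) -> dict[int, float]:
    """Arithmetic mean of ``values`` per zone label (nodata excluded).

    A zone whose cells are all nodata gets ``nan`` (reported as missing).
    """
    out: dict[int, float] = {}
    vals = values.values.astype(float)
    ok = values.valid_mask & np.isfinite(vals)
    for lab in zones.areas:
        sel = (zones.labels == lab) & ok
        out[lab] = float(vals[sel].mean()) if sel.any() else float("nan")
    return out


# -- vector → raster --------------------------------------------------------


def rasterize_points(r: RasterGrid, points) -> np.ndarray:
    """Boolean mask of cells containing any of the shapely points/(x, y) pairs."""
    mask = np.zeros(r.shape, dtype=bool)
    nrow, ncol = r.shape
    for p in points:
        x, y = (p.x, p.y) if hasattr(p, "x") else (p[0], p[1])
        row, col = r.cell_of(x, y)
        if 0 <= row < nrow and 0 <= col < ncol:
            mask[row, col] = True
    return mask


def rasterize_lines(r: RasterGrid, lines) -> np.ndarray:
    """Boolean mask of cells crossed by shapely LineStrings.

    Lines are densified to half a cell size so no crossed cell is skipped.
    """
    mask = np.zeros(r.shape, dtype=bool)
    nrow, ncol = r.shape
    step = r.cell_size / 2.0
    for line in lines:
        length = line.length
        if length == 0:
            continue
        n = max(int(np.ceil(length / step)) + 1, 2)
        for frac in np.linspace(0.0, 1.0, n):
            pt = line.interpolate(frac, normalized=True)
            row, col = r.cell_of(pt.x, pt.y)
            if 0 <= row < nrow and 0 <= col < ncol:
                mask[row, col] = True
    return mask


def rasterize_polygons(r: RasterGrid, polygons) -> np.ndarray:
    """Boolean mask of cells whose centre falls inside any polygon."""
    from shapely import contains_xy
    from shapely.ops import unary_union

    polys = list(polygons)
    if not polys:
        return np.zeros(r.shape, dtype=bool)
    merged = unary_union(polys)
    xs, ys = r.cell_centers()
    return contains_xy(merged, xs, ys)


# -- plain-text raster I/O (ESRI ASCII grid) ---------------------------------

_NODATA = -9999.0


def write_ascii_grid(r: RasterGrid, path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc), nodata tag honoured."""
    nrow, ncol = r.shape
    x0, y0 = r.origin
    yll = y0 - nrow * r.cell_size
    vals = np.where(r.nodata_mask, _NODATA, r.values.astype(float))
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {x0}\nyllcorner {yll}\n"
        f"cellsize {r.cell_size}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    ncol, nrow = int(header["ncols"]), int(header["nrows"])
    vals = vals.reshape(nrow, ncol)
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _NODATA)
    mask = vals == nodata
    origin = (header["xllcorner"], header["yllcorner"] + nrow * cell)
    out = vals.astype(float)
    out[mask] = np.nan
    return RasterGrid(out, cell, origin, mask)
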