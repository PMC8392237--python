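"""Ecological-source selection.

Ecological importance is the equal-weight mean of the min-max-normalized
integrated-service and integrated-sensitivity surfaces, classified into
four quantile levels (non / slightly / moderately / extremely important).
Source candidates are the extremely-important cells unioned with the
rasterized statutory reserve ("ecological red line") polygons; candidates
are split into 8-connected patches and patches smaller than the minimum
area (default 10 km²) are dropped — unless they intersect the red line,
which is protected wholesale regardless of size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import (
    PatchLabeling,
    RasterGrid,
    connected_patches,
    minmax_normalize,
    quantile_classify,
    rasterize_polygons,
)

log = logging.getLogger(__name__)

__all__ = ["SourcePatch", "ecological_importance", "select_sources"]

IMPORTANCE_LEVELS = {
    1: "non-important", 2: "slightly important",
    3: "moderately important", 4: "extremely important",
}


@dataclass
class SourcePatch:
    """One ecological-source patch: mask, area, centroid, red-line flag."""

    id: int
    mask: np.ndarray
    area_km2: float
    centroid: tuple[float, float]  # map coordinates (x, y)
    from_redline: bool

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def ecological_importance(
    services: RasterGrid, sensitivity: RasterGrid
) -> tuple[RasterGrid, RasterGrid]:
    """0.5·norm(services) + 0.5·norm(sensitivity), plus 4 quantile classes."""
    services.require_congruent(sensitivity, "sensitivity")
    ns, nv = minmax_normalize(services), minmax_normalize(sensitivity)
    mask = ns.nodata_mask | nv.nodata_mask
    idx = 0.5 * np.nan_to_num(ns.values, nan=0.0) + 0.5 * np.nan_to_num(nv.values, nan=0.0)
    idx[mask] = np.nan
    index = services.with_values(idx, mask)
    return index, quantile_classify(index, 4)


def select_sources(
    importance_classes: RasterGrid,
    redline: list | None = None,
    min_area_km2: float = 10.0,
    top_classes: int = 1,
) -> list[SourcePatch]:
    """Select ecological-source patches from the importance classification.

    Candidates = (importance class in the top ``top_classes`` levels) ∪
    rasterized red-line polygons; 8-connected patches below ``min_area_km2``
    are dropped unless they intersect the red line.  Patches are returned
    sorted by area, largest first.
    """
    if min_area_km2 <= 0:
        raise ValueError("min_area_km2 must be > 0")
    classes = importance_classes.values.astype(int)
    # classes live on the fixed 4-level importance scale
    top = (classes > 4 - top_classes) & importance_classes.valid_mask

    red_mask = np.zeros(importance_classes.shape, dtype=bool)
    if redline:
        red_mask = rasterize_polygons(importance_classes, redline) & importance_classes.valid_mask

    candidates = top | red_mask
    labeling = connected_patches(importance_classes, candidates, connectivity=8)

    xs, ys = importance_classes.cell_centers()
    patches: list[SourcePatch] = []
    for lab, area in labeling.areas.items():
        mask = labeling.mask_of(lab)
        on_redline = bool((mask & red_mask).any())
        if area < min_area_km2 and not on_redline:
            continue
        cx = float(xs[mask].mean())
        cy = float(ys[mask].mean())
        patches.append(SourcePatch(0, mask, float(area), (cx, cy), on_redline))

    if not patches:
        raise ValueError(
            "no source patch survives the area filter; relax min_area_km2 or "
            "widen top_classes"
        )
    patches.sort(key=lambda p: -p.area_km2)
    for i, p in enumerate(patches, start=1):
        p.id = i
    log.info("selected %d source patches, %.2f km2 total",
             len(patches), sum(p.area_km2 for p in patches))
    return patches
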