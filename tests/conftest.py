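import numpy as np
import pytest

from ecolink.grid import RasterGrid, connected_patches, rasterize_polygons
from ecolink.sources import SourcePatch
from ecolink.synthetic import make_fixture


def grid_of(values, cell_size=30.0, nodata_mask=None):
    """Shorthand RasterGrid constructor used across the suite."""
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, cell_size=cell_size,
                      origin=(0.0, values.shape[0] * cell_size),
                      nodata_mask=nodata_mask)


def patches_from_reserves(bundle) -> list[SourcePatch]:
    """Turn each reserve polygon of a fixture bundle into a SourcePatch."""
    patches = []
    for i, poly in enumerate(bundle.reserves, start=1):
        mask = rasterize_polygons(bundle.lulc, [poly]) & bundle.lulc.valid_mask
        lab = connected_patches(bundle.lulc, mask)
        area = sum(lab.areas.values())
        xs, ys = bundle.lulc.cell_centers()
        patches.append(SourcePatch(
            id=i, mask=mask, area_km2=area,
            centroid=(float(xs[mask].mean()), float(ys[mask].mean())),
            from_redline=True,
        ))
    return patches


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hourglass():
    return make_fixture("hourglass", shape=(40, 60))


@pytest.fixture
def wall():
    return make_fixture("wall", shape=(40, 60))
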