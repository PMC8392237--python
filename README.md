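# ecolink

Ecological security patterns (ESPs) on raster landscapes: a tested,
reusable Python implementation of the source–resistance–corridor workflow
used in regional conservation planning — for landscape ecologists,
spatial-planning researchers, and anyone who wants the full chain from
ecosystem-service rasters to prioritized ecological corridors runnable and
checkable at desk scale.

## What it computes

1. **Ecosystem services.** Habitat quality follows the InVEST model: each
   threat *r* decays with distance (linear `i = 1 − d/d_max` or exponential
   `i = exp(−(2.99/d_max)·d)`, zero beyond *d_max*), degradation is the
   weight-normalized average `D = Σ_r (W_r/ΣW)·i_r·S_jr`, and quality is the
   half-saturation decay `Q = H_j·(1 − D^z/(D^z + k^z))` with *z* = 2.5.
   Annual water yield is the pixel water balance `Y = (1 − AET/P)·P`, and
   carbon storage is a per-cover sum over four pools (above-ground,
   below-ground, soil, dead matter).
2. **Ecological sensitivity.** Ordinal {7,5,3,1} step-function scores for
   habitat sensitivity (distance to major roads and reserves, land cover,
   NDVI) and water sensitivity (distance to surface water, wastewater and
   air-pollution sources), plus soil loss from the Chinese Soil Loss
   Equation `A = R·K·LS·C·P·T`.
3. **Ecological sources.** Equal-weight min–max combination of the service
   and sensitivity surfaces, quartile classification, union with statutory
   reserve ("red line") polygons, connected-component labelling, and a
   10 km² minimum-area filter (red-line patches exempt).
4. **Resistance surface.** Weighted six-factor overlay (land cover 0.30;
   relief, slope, distance to class-I and class-II roads 0.15 each;
   distance to pollution sources 0.10) with tabulated per-class resistance
   values; the most permeable combination scores exactly 1, the least 370.
5. **Connectivity.** On the 8-neighbour cost graph (edge cost = mean cell
   resistance × distance): cost-weighted distances, least-cost corridors
   between source pairs, circuit-theory current maps (cell conductance =
   1/resistance, Kirchhoff solve per source pair), current-flow centrality
   of the source network, moving-window barrier detection (200–1000 m
   radii), pinch points, and an improvement × priority (L/M/H/V) composite
   corridor prioritization.

A seeded synthetic-landscape generator (clustered land cover, smooth
terrain and climate fields, roads, pollution points, reserve polygons)
stands in for regional GIS stacks, and planted-structure fixtures
("hourglass" bottleneck, "wall" barrier) make the connectivity stages
falsifiable.

## Worked example

```sh
ecolink run-all --seed 0 --out runs/demo
```

runs the bundled 120 × 120-cell (100 m) demo landscape end-to-end and
prints per-stage statistics; `runs/demo/report.json` then holds

```json
{
 "seed": 0,
 "n_sources": 5,
 "source_area_km2": 40.71,
 "n_corridors": 7,
 "total_corridor_length_km": 12.95,
 "priority_corridors": 0,
 "composition_percent": {"paddy_field": 38.99, "irrigated_land": 41.06,
                         "forestland": 16.01, "river": 2.58, "lake": 1.16,
                         "urban_construction_land": 0.19}
}
```

— five source patches (40.7 km² in a 144 km² landscape), seven least-cost
corridors totalling 13.0 km, and the land-cover composition of the 1-km
corridor buffers (mostly cropland, as expected on a cropland-dominated
plain). The run directory also contains every intermediate raster
(`habitat_quality.asc`, `resistance.asc`, `improvement_score.asc`, ...),
`corridors.geojson`/`corridors.csv` with per-corridor cost, length,
centrality and L/M/H/V levels, the top-40 `barriers.csv` and
`pinch_points.csv` tables, and a `manifest.json` recording the config
hash and seed.

The same pipeline is available as a library:

```python
from ecolink.pipeline import demo_config, run
result = run(demo_config(seed=0))
print(len(result.sources), len(result.corridors))
```

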