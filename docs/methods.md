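# Methods

This note documents the models implemented in `ecolink`, the choices made
where the workflow's published descriptions leave details open, and what
the synthetic landscapes do and do not establish about real data.

## Raster conventions

All layers of one analysis share shape, cell size and top-left origin
(`RasterGrid`). Grids are row-major; distances are metres between cell
centres; areas are km² (cell count × cell_size²/10⁶). Nodata propagates
through every cellwise operation. Three deliberate conventions:

- **Constant rasters min–max-normalize to 0**, not NaN, with a logged
  warning, so equal-weight sums over normalized layers stay defined on
  degenerate inputs.
- **Quantile classification is rank-based with ties to the lower class**:
  a cell's class is determined by the minimum rank of its value, so the
  map is a monotone step function of the value, class counts are equal up
  to ties, and a constant raster is all class 1. The same rule orders
  corridor-level quartiles (L/M/H/V), so a single corridor is "L".
- **Interval classifications are half-open `[lo, hi)`** throughout
  (sensitivity scores, resistance classes). Published break tables mix
  `[..]` and `(..]` conventions; a single convention changes assignments
  only at exact break values, which have measure zero on continuous axes.
- Focal relief uses a square window, default 3×3 cells (no window size is
  standard; it is configurable). Slope is the arctangent of the central
  finite-difference gradient magnitude, in degrees.

## Ecosystem services

**Habitat quality** (InVEST formulation). Threat impact at distance *d*:
linear `1 − d/d_max` or exponential `exp(−(2.99/d_max)·d)`, both with a
hard cutoff to 0 beyond *d_max* — "maximum effective distance" is read as
literally maximal. The exponential's published form in the source workflow
is sometimes printed with *d* and *d_max* transposed, which would grow
with distance and diverge at zero; the standard decaying form is used.
Degradation is `D = Σ_r (W_r/ΣW_r)·i_r·β·S_jr` with β = 1. The per-threat
impact `i_r` is evaluated at the **distance to the nearest source cell**
of that threat rather than summed over all source cells: the
weight-normalization already makes *D* a weighted average of threat
levels, and the nearest-source reading is scale-free (independent of how
many raster cells discretize one city). A clipped all-source summation
mode is available (`degradation(..., mode="sum")`). Quality is
`Q = H_j·(1 − D^z/(D^z + k^z))` with *z* = 2.5 and half-saturation
*k* = 0.5 by default (*k* is rarely reported; 0.5 centres the response on
the [0, 1] degradation scale and is configurable).

**Water yield** is the exact pixel balance `Y = P − AET`, with `Y = 0`
where `P = 0`. AET is an input raster; no Budyko-type evapotranspiration
model is fitted, because the workflow this implements supplies AET rather
than its parameters.

**Carbon storage** is a per-cover lookup of the four-pool sum. The default
suitability/sensitivity/carbon tables are typical InVEST-style values for
a cropland-dominated subtropical plain and are editable — they are
illustrative defaults, not calibrated estimates.

## Ecological sensitivity

Habitat and water sensitivity are ordinal overlays on the {7,5,3,1} scale
with the break tables shipped as defaults (distance to major roads,
reserves, surface water, wastewater and air-pollution sources; land-cover
class; NDVI). Sub-scores combine by **unweighted arithmetic mean**, which
keeps the result on the 1–7 scale; "overlay" descriptions rarely state an
aggregation rule, and a `sum` mode is provided. Soil loss is the CSLE
factor product `A = R·K·LS·C·P·T`; the factor rasters are pipeline inputs.
For synthetic landscapes they are derived by proxy: R scales with annual
precipitation, K varies weakly and inversely with NDVI, LS uses a
one-cell slope-length approximation, and C/P/T are land-cover lookups.
Integration is min–max normalization, equal-weight mean, and quartile
classification — so the integrated index is invariant to affine rescaling
of any input layer, and soil loss needs no separate pre-normalization.

## Source selection

Ecological importance = 0.5·norm(services) + 0.5·norm(sensitivity),
classified into quartiles. Candidates are the top quartile
("extremely important"; configurable to the top two) unioned with
rasterized red-line polygons. Patches are 8-connected components;
patches below 10 km² are dropped **unless they intersect the red line** —
statutory reserves dominate real source networks (≈81 % of source area in
the motivating study), implying they are retained wholesale, so size
filtering is applied only to non-reserve candidates.

## Resistance surface

The six-factor table (weights 0.30/0.15/0.15/0.15/0.15/0.10) is shipped
verbatim, with two repairs: the pollution-distance rows skip the
4–6 km span as printed, so the breaks are read gap-free as
(0, 2000, 4000, 8000, 10000, ∞) → (100, 80, 60, 40, 1); and values above
the top printed interval (slope > 47°, relief > 239 m) clamp to the last
class. The analytic bounds of the weighted overlay are [1, 370]. The
motivating study prints a maximum of 441.40, which is not achievable from
its own weights and class values (0.3·1000 + 4·0.15·100 + 0.1·100 = 370);
the implementation follows the table and documents the discrepancy rather
than rescaling to match.

## Connectivity

**Graph.** One node per valid cell, 8-neighbour edges, edge cost = mean of
the two cell resistances × centre-to-centre distance (×√2 diagonal) — the
standard raster-graph convention; conductance is the reciprocal.

**Corridors.** CWD fields are multi-source Dijkstra distances (patch cells
at 0); LCPs are recovered by predecessor backtracking, so
`lcp_cost(A,B) = min over B of CWD_A` and symmetry holds. Source pairing
follows the Linkage-Mapper-style adjacency rule: keep mutually-nearest
pairs plus every pair whose LCP does not cross a third patch (a study with
48 sources and 91 corridors clearly pruned the 1 128 possible pairs);
`pairing="all"` disables pruning. The corridor swath is
`CWD_A + CWD_B − lcp_cost ≤ t` with *t* defaulting to the cost of stepping
half the 1 km corridor width off the path and back on the lattice
(`2(√2−1)·500 m · min resistance`); a fixed 1-km buffered LCP is also
emitted and used for the land-composition report.

**Circuit solves.** Patches collapse to supernodes; the Laplacian system
with 1 A injected is solved sparsely (ground = patch B); per-cell current
is half the sum of absolute incident edge currents; effective resistance
is the supernode potential. Kirchhoff residuals at free nodes are checked
(< 10⁻⁸ in the acceptance suite). Centrality treats each source as a node
and each corridor as a resistor equal to its LCP cost, accumulating
absolute currents over all-pairs unit injections, per connected component.

**Barriers.** Moving-window restoration scan at every radius that is a
multiple of the cell size in [200 m, 1000 m]. Restoring a window to the
landscape minimum resistance lets movement reach the window at the lowest
CWD on its rim and cross it at minimum cost, so the restored least-cost
distance at centre *c* is `min_w(CWD_A) + min_w(CWD_B) + 2r·R_min`, with
window minima computed by separable square-window minimum filters (the
moving-window formulation of the Barrier Mapper method; square windows
keep the scan O(cells) per radius). The improvement score is
`IS = max(0, lcp_cost − restored)/(2r)` — cost saved per metre of restored
diameter — and each cell keeps its best score over radii and pairs. On a
uniform landscape already at minimum resistance IS ≡ 0 identically.

**Pinch points** are the top-N cells of the per-cell maximum pairwise
current within corridor swaths. Both top-40 lists use greedy non-maximum
suppression with a 1 km radius (ties broken by cell index) so the listed
locations are distinct. Corridor **improvement level** is the quartile of
zonal mean IS over the swath; **priority level** is the quartile of zonal
max current; the composite label is "improvement&priority" (e.g. "V&V"
for priority corridors).

## Synthetic landscapes

Random fields are Gaussian-smoothed white noise with a configured
correlation length — the simplest generator with controllable spatial
autocorrelation. Land cover thresholds one field at the cumulative
class-proportion quantiles, so realized shares match requested ones up to
ties; the default proportions follow a cropland-dominated alluvial plain
(≈62 % cropland, 16 % forest, 13 % water, 8 % built). AET is generated as
precipitation × a smooth factor in [0.2, 0.9], so the water-balance
invariant 0 ≤ AET ≤ P holds by construction. Roads are jittered
edge-to-edge polylines; pollution plants are uniform points (alternately
assigned to the wastewater and air classes); reserves are buffered random
points. Everything is reproducible from a single integer seed.

What the generator does **not** emulate: hydrologically consistent
terrain/drainage, road-network topology, realistic city shapes, or the
spatial covariances between land cover, climate and soils found in real
regions. Passing tests therefore establish the correctness of the
algorithms and the internal consistency of the workflow — not the
ecological validity of any particular parameter table on real landscapes.

The planted fixtures make the connectivity claims falsifiable: in
"hourglass" every unit of injected current must cross the designed
one-cell bridge (the matrix is nodata), so the bridge must appear as the
rank-1 pinch point at current 1.0; in "wall" every left–right path pays
the wall, and the top barrier window must overlap it with a score that
matches an independent 1-D transect computation exactly.

## Problem sizes and numerics

The test and demonstration configurations use 40×60 to 200×200 grids, at
which every stage (including ~20 000-node sparse circuit solves and
27-radius barrier scans) runs in seconds; the methodology is unchanged at
larger extents. Sparse solves use SuperLU via `scipy.sparse.linalg.spsolve`;
disconnected source pairs are detected (non-finite solves) and reported
rather than silently dropped; zero-valued or constant layers follow the
degenerate-input rules above.

## Known limitations

- Circuit analysis is pairwise (and coarse all-pairs for centrality); no
  all-to-ground or wall-to-wall modes.
- The barrier scan's window formulation is an upper-bound approximation
  to exact per-window graph re-solving (exact on transect-like
  geometries, as the wall fixture verifies).
- No CRS handling, reprojection or resampling: all layers must already be
  congruent.
- Default parameter tables are illustrative, not calibrated; every table
  is overridable in the pipeline config or in code.
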